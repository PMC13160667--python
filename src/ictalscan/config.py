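"""Run-level configuration and reproducibility plumbing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide parameters shared by all CLI stages."""

    fs: float = 500.0
    epoch_s: float = 10.0
    interval_s: float = 1800.0
    freq_band: tuple[float, float] = (1.0, 100.0)
    n_freqs: int = 96
    threshold: float = 0.99
    backbone: str = "mlp"
    image_size: tuple[int, int] = (224, 224)
    seed: int = 0
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.interval_s % self.epoch_s:
            raise ValueError("epoch_s must divide interval_s")
        lo, hi = self.freq_band
        if not (0 < lo < hi <= self.fs / 2):
            raise ValueError("freq_band must lie within (0, fs/2]")


def run_manifest(config: RunConfig, extra: dict | None = None) -> dict:
    """Reproducibility stamp: config hash, seed, library versions."""
    import numpy, scipy, sklearn  # local to keep import light

    cfg = dataclasses.asdict(config)
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "python": platform.python_version(),
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_run_manifest(manifest: dict, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
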