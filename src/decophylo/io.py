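"""Plain-text input/output: tip-range tables and YAML run configuration.

All tabular artifacts are UTF-8 TSV with a header row; leading ``#`` comment
lines (used for provenance headers) are skipped on read.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import yaml

from .dec import EpochConfig
from .errors import FormatError, ParameterError
from .statespace import RangeStateSpace

__all__ = ["read_tip_ranges", "write_tip_ranges", "load_dec_config"]


def read_tip_ranges(path) -> dict[str, tuple[str, ...]]:
    """Read a two-column TSV: tip label, comma-separated area codes."""
    out: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if header[:2] != ["tip", "range"]:
                    raise FormatError(f"unexpected tip-range header: {header}")
                continue
            tip, rng = line.split("\t")[:2]
            out[tip] = tuple(a for a in rng.split(",") if a)
    return out


def write_tip_ranges(tip_ranges: Mapping[str, tuple[str, ...]], path, comment=None):
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("tip\trange\n")
        for tip in sorted(tip_ranges):
            fh.write(f"{tip}\t{','.join(tip_ranges[tip])}\n")


def load_dec_config(path) -> dict:
    """Load areas, adjacency, max range size and epochs from a YAML file.

    Schema::

        areas: [A, B, C]
        max_range_size: 2
        adjacency: complete          # or an explicit 0/1 matrix
        epochs:                      # optional; single uniform epoch if absent
          boundaries: [2.5, 0.01, 0]
          multipliers: [1.0, 5.0, 1.0]   # scalars or full matrices per epoch

    Returns ``{"space": RangeStateSpace, "epochs": EpochConfig}``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "areas" not in cfg:
        raise FormatError("config must be a mapping with an 'areas' list")
    areas = [str(a) for a in cfg["areas"]]
    n = len(areas)
    max_range = int(cfg.get("max_range_size", 2))
    adj_cfg = cfg.get("adjacency", "complete")
    if adj_cfg == "complete" or adj_cfg is None:
        adjacency = None
    else:
        adjacency = np.asarray(adj_cfg)
    space = RangeStateSpace(areas, max_range, adjacency)
    epochs_cfg = cfg.get("epochs")
    if epochs_cfg is None:
        epochs = EpochConfig.uniform(n)
    else:
        boundaries = [float(b) for b in epochs_cfg["boundaries"]]
        mats = []
        for m in epochs_cfg["multipliers"]:
            if np.isscalar(m):
                mats.append(np.full((n, n), float(m)))
            else:
                mat = np.asarray(m, dtype=float)
                if mat.shape != (n, n):
                    raise ParameterError(
                        f"multiplier matrix has shape {mat.shape}, expected {(n, n)}"
                    )
                mats.append(mat)
        epochs = EpochConfig(boundaries, mats)
    return {"space": space, "epochs": epochs}
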