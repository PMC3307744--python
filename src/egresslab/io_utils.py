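"""Small output plumbing: versioned CSV/JSON artifacts.

Every file the pipeline writes embeds the package version and the seed that
produced it, either as ``#``-prefixed header lines (CSV) or as top-level
keys (JSON), so any artifact can be traced back to its run.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def _version() -> str:
    from . import __version__
    return __version__


def write_csv(df: pd.DataFrame, path, seed: int | None = None,
              index: bool = False, **meta) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [f"# egresslab {_version()}"]
    if seed is not None:
        header.append(f"# seed={seed}")
    for k, v in meta.items():
        header.append(f"# {k}={v}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, index=index)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(obj: dict, path, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"egresslab_version": _version()}
    if seed is not None:
        payload["seed"] = seed
    payload.update(obj)
    path.write_text(json.dumps(payload, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    import numpy as np
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
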