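"""Byte-stable structured-text serialization for run artifacts.

Floats are rounded to 12 significant digits before dumping and keys are
sorted, so two runs with identical config and seed produce byte-identical
JSON artifacts.
"""

from __future__ import annotations

import json

import numpy as np


def _round12(obj):
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round12(obj.tolist())
    if isinstance(obj, dict):
        return {str(k): _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_round12(v) for v in seq]
    return obj


def dump_json(obj, path=None) -> str:
    text = json.dumps(_round12(obj), sort_keys=True, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def load_json(path):
    with open(path) as fh:
        return json.load(fh)
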