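"""Structured run configuration: YAML tree with strict key validation.

Unknown keys are rejected with an error naming every offending key, and every
run writes its resolved configuration next to its outputs for provenance.
"""
from __future__ import annotations

import json
from pathlib import Path

import yaml

# allowed keys per section; None means scalar leaf
SCHEMA: dict = {
    "seed": None,
    "out_dir": None,
    "log_level": None,
    "data": {"dir": None, "num_classes": None, "n_train": None,
             "n_test": None, "canvas_side": None, "items_min": None,
             "items_max": None, "seed": None},
    "model": {"num_classes": None, "neck": None, "attention": None,
              "seed": None},
    "train": {"epochs": None, "batch_size": None, "base_lr": None,
              "momentum": None, "weight_decay": None, "poly_power": None,
              "input_side": None},
    "eval": {"checkpoint": None, "input_side": None, "empty_union": None,
             "split": None},
    "uncertainty": {"checkpoint": None, "lambda_hat": None,
                    "input_side": None},
    "nutrition": {"mask": None, "table": None, "margin": None},
    "complexity": {"side": None, "convention": None},
}


def _collect_unknown(tree: dict, schema: dict, prefix: str = "") -> list[str]:
    bad = []
    for key, value in tree.items():
        if key not in schema:
            bad.append(prefix + key)
            continue
        sub = schema[key]
        if isinstance(value, dict):
            if not isinstance(sub, dict):
                bad.append(prefix + key)
            else:
                bad.extend(_collect_unknown(value, sub, prefix + key + "."))
    return bad


def validate_config(tree: dict) -> dict:
    bad = _collect_unknown(tree or {}, SCHEMA)
    if bad:
        raise ValueError("unknown configuration keys: " + ", ".join(sorted(bad)))
    return tree or {}


def load_config(path: str | Path) -> dict:
    tree = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(tree, dict):
        raise ValueError("configuration root must be a mapping")
    return validate_config(tree)


def write_resolved(tree: dict, out_dir: str | Path,
                   name: str = "resolved_config.json") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = out / name
    p.write_text(json.dumps(tree, indent=1, default=str))
    return p
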