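"""Run configuration: a validated, flat-namespaced parameter set.

Configs are nested mappings with fixed sections (``plate``, ``graph``,
``pattern``, ``anneal``, ``expression``, ``spots``) plus top-level
``seed`` and ``outdir``.  Unknown keys are rejected; every run echoes the
fully resolved configuration (defaults filled in) to disk.  JSON, YAML,
and TOML are accepted on read; YAML is the canonical write dialect.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

from .errors import ConfigError

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "stforge_run",
    "plate": {
        "n": 1000,
        "mode": "random",  # random | grid
        "dim": 2,
        "bounds": None,  # per-axis [min, max]; default unit square/cube
    },
    "graph": {
        "method": "knn",  # knn | radius | delaunay | snn
        "param": 6,  # k or r
        "metric": "euclidean",
    },
    "pattern": {
        "mode": "attractive",  # predefined mode or custom
        "n_types": 3,
        "dominant_prob": 0.8,
        "proportions": None,  # default uniform
        "transition": None,  # required for mode=custom
        "group_assignment": None,  # repulsive mode
        "n_layers": None,  # layered/gyrus; default n_types
        "type_names": None,
    },
    "anneal": {
        "method": "bsa",  # gsa | lsa | bsa
        "alpha": 0.95,
        "tmin_frac": 1e-4,
        "stall_limit": 200,
        "max_temps": 400,
    },
    "expression": {
        "source": "simulate",  # simulate | reference | none
        "n_genes": 200,
        "n_cells_per_type": 100,
        "baseline_mean": 2.0,
        "dispersion": 2.0,
        "marker_fold": 8.0,
        "n_markers_per_type": 20,
        "reference_matrix": None,  # Matrix Market path (genes x cells)
        "reference_genes": None,
        "reference_labels": None,
    },
    "spots": {
        "enabled": False,
        "shape": "rectangle",  # circle | rectangle
        "size": 0.1,
        "lattice": "square",  # square | hexagonal
    },
}


def resolve_config(user: dict | None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    cfg = copy.deepcopy(DEFAULTS)
    user = user or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a mapping")
    for key, val in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for k2, v2 in val.items():
                if k2 not in cfg[key]:
                    raise ConfigError(f"unknown config key {key}.{k2}")
                cfg[key][k2] = v2
        else:
            cfg[key] = val
    return cfg


def load_config(path) -> dict:
    """Read a config file (JSON / YAML / TOML by suffix) and resolve it."""
    path = Path(path)
    text = path.read_text()
    suffix = path.suffix.lower()
    try:
        if suffix in (".yaml", ".yml"):
            import yaml

            user = yaml.safe_load(text)
        elif suffix == ".toml":
            import tomllib

            user = tomllib.loads(text)
        else:
            user = json.loads(text)
    except Exception as exc:
        raise ConfigError(f"{path}: cannot parse: {exc}") from exc
    return resolve_config(user)


def dump_config(cfg: dict, path) -> None:
    """Write a resolved config in the canonical dialect (YAML)."""
    import yaml

    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
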