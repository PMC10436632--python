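"""Pipeline configuration: documented defaults, validation, suggestions.

Configuration is a flat mapping of dotted keys (``dbscan.eps``,
``lk.window`` ...).  YAML documents may nest sections instead
(``dbscan: {eps: 12}``); they are flattened on validation.  Unknown keys
are rejected with the nearest valid name suggested, and all problems are
reported at once.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from typing import Any

from .errors import ConfigError

#: key -> (default, allowed types, documentation)
DEFAULTS: dict[str, tuple[Any, tuple[type, ...], str]] = {
    "input": (None, (str,), "input path: multi-frame DICOM file or image directory"),
    "out": (None, (str,), "output directory for CSV/JSON results"),
    "frame_interval": (None, (int, float), "seconds per frame (required for image directories, overrides DICOM metadata when set)"),
    "seed": (0, (int,), "global RNG seed; stage seeds derive from it"),
    "verbosity": ("info", (str,), "logging level: debug|info|warning"),
    "threshold.mode": ("auto", (str,), "threshold selection: auto (Otsu) or manual"),
    "threshold.value": (None, (int, float), "manual threshold T (used when mode=manual)"),
    "seed_points.n": (300, (int,), "number of random tracking points seeded in the band"),
    "seed_points.seed": (None, (int,), "seeding RNG seed; derived from the global seed when unset"),
    "dbscan.eps": (15.0, (int, float), "DBSCAN neighbourhood radius in pixels"),
    "dbscan.min_pts": (10, (int,), "DBSCAN core-point neighbour count (point itself included)"),
    "dbscan.keep_all_clusters": (False, (bool,), "keep every non-noise cluster instead of only the largest"),
    "lk.window": (15, (int,), "LK window side m (odd); the solve uses n = m^2 pixels"),
    "lk.pyramid_levels": (3, (int,), "coarse-to-fine pyramid depth; 1 = plain single-level LK"),
    "lk.iterations": (5, (int,), "Gauss-Newton refinements per pyramid level (early exit at 0.01 px)"),
    "lk.min_eig_floor": (None, (int, float), "absolute floor for the smaller structure-matrix eigenvalue; default 1e-4 * m^2"),
    "lk.max_condition": (1e6, (int, float), "structure-matrix condition cap beyond which a point is invalidated"),
    "groups.k": (15, (int,), "number of along-band groups whose centroids define the band length"),
    "smooth.kernel": (5, (int,), "uniform smoothing kernel size (odd)"),
    "cycles.curve": ("cumulative_v", (str,), "curve used for cycle detection: cumulative_v|cumulative_h|gs"),
    "cycles.min_prominence": (None, (int, float), "minimum extremum prominence; default 10% of the curve range"),
    "drift.enabled": (True, (bool,), "apply first-cycle-anchored linear drift correction"),
}

_CYCLE_CURVES = ("cumulative_v", "cumulative_h", "gs")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with dict-style access."""

    values: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def get(self, key: str, default: Any = None) -> Any:
        return self.values.get(key, default)

    def to_dict(self) -> dict[str, Any]:
        return dict(self.values)


def _flatten(raw: dict, prefix: str = "") -> dict[str, Any]:
    flat: dict[str, Any] = {}
    for key, value in raw.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, prefix=f"{name}."))
        else:
            flat[name] = value
    return flat


def validate_config(raw: dict | None = None) -> PipelineConfig:
    """Fill defaults, type-check and reject unknown keys.

    All problems are collected and reported in a single
    :class:`~diaflow.errors.ConfigError`.
    """
    flat = _flatten(raw or {})
    problems: list[str] = []
    values = {key: default for key, (default, _, _) in DEFAULTS.items()}

    for key, value in flat.items():
        if key not in DEFAULTS:
            hint = difflib.get_close_matches(key, DEFAULTS.keys(), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            problems.append(f"unknown key {key!r}{suggestion}")
            continue
        _, types, _ = DEFAULTS[key]
        if value is not None and not isinstance(value, types):
            # bool is an int subclass; reject bools where ints are expected
            if isinstance(value, bool) and bool not in types:
                problems.append(f"{key}: expected {types[0].__name__}, got bool")
                continue
            problems.append(
                f"{key}: expected {'/'.join(t.__name__ for t in types)}, "
                f"got {type(value).__name__} ({value!r})"
            )
            continue
        values[key] = value

    if values["threshold.mode"] not in ("auto", "manual"):
        problems.append("threshold.mode: must be 'auto' or 'manual'")
    if values["threshold.mode"] == "manual" and values["threshold.value"] is None:
        problems.append("threshold.value: required when threshold.mode is 'manual'")
    for key in ("lk.window", "smooth.kernel"):
        v = values[key]
        if isinstance(v, int) and v % 2 == 0:
            problems.append(f"{key}: must be odd, got {v}")
    if values["cycles.curve"] not in _CYCLE_CURVES:
        problems.append(f"cycles.curve: must be one of {_CYCLE_CURVES}")

    if problems:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(problems))
    return PipelineConfig(values=values)
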