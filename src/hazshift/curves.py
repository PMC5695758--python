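"""Age curves: declarative specs mapping child age (days) to a value.

Curves parameterise the synthetic survey generator: the true mean HAZ
trajectory, the true biological SD trajectory, and the age-specific
measurement-error SD. A curve spec is either a Python callable
``age_days -> value`` (vectorised over numpy arrays) or a small dict:

* ``{"kind": "constant", "value": v}``
* ``{"kind": "linear", "age0": a0, "value0": v0, "age1": a1, "value1": v1}``
  (linearly interpolated, clamped to the endpoint values outside [a0, a1])
* ``{"kind": "piecewise_linear", "ages_days": [...], "values": [...]}``

Dict specs round-trip through YAML config files; callables are for
programmatic use.
"""

from __future__ import annotations

from typing import Callable, Mapping, Union

import numpy as np

from hazshift.errors import ConfigurationError

CurveSpec = Union[Callable[[np.ndarray], np.ndarray], Mapping]


def curve_from_spec(spec: CurveSpec) -> Callable[[np.ndarray], np.ndarray]:
    """Turn a curve spec into a vectorised callable of age in days."""
    if callable(spec):
        return lambda age: np.asarray(spec(np.asarray(age, dtype=float)), dtype=float)
    if not isinstance(spec, Mapping):
        raise ConfigurationError(f"curve spec must be callable or mapping, got {type(spec)!r}")
    kind = spec.get("kind")
    if kind == "constant":
        value = float(spec["value"])
        return lambda age: np.full_like(np.asarray(age, dtype=float), value)
    if kind == "linear":
        a0, a1 = float(spec["age0"]), float(spec["age1"])
        v0, v1 = float(spec["value0"]), float(spec["value1"])
        if a1 <= a0:
            raise ConfigurationError("linear curve requires age1 > age0")
        return lambda age: np.interp(np.asarray(age, dtype=float), [a0, a1], [v0, v1])
    if kind == "piecewise_linear":
        ages = np.asarray(spec["ages_days"], dtype=float)
        values = np.asarray(spec["values"], dtype=float)
        if ages.ndim != 1 or ages.shape != values.shape or ages.size < 2:
            raise ConfigurationError("piecewise_linear needs matching 1-d ages_days/values, length >= 2")
        if np.any(np.diff(ages) <= 0):
            raise ConfigurationError("piecewise_linear ages_days must be strictly increasing")
        return lambda age: np.interp(np.asarray(age, dtype=float), ages, values)
    raise ConfigurationError(f"unknown curve kind {kind!r}")


def validate_nonnegative(spec: CurveSpec, age_range: tuple[float, float], name: str) -> None:
    """Check a curve is >= 0 on an integer-day grid over *age_range*."""
    fn = curve_from_spec(spec)
    grid = np.arange(int(age_range[0]), int(np.ceil(age_range[1])))
    vals = fn(grid)
    if np.any(vals < 0):
        raise ConfigurationError(f"{name} curve is negative at some ages (SDs must be >= 0)")
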