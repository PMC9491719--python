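"""Named, strictly positive parameter vectors with a log-space view.

All sensitivity analysis in this package happens in the space of natural
logarithms of the parameters, which requires every parameter to be strictly
positive.  :class:`ParameterSet` is the single container used to pass
parameter values around; models look parameters up by name, so the internal
ordering of a ParameterSet never affects model output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["ParameterSet"]


@dataclass(frozen=True)
class ParameterSet:
    """An ordered set of named, strictly positive parameter values.

    Parameters
    ----------
    names
        Unique parameter identifiers, in a fixed order.
    values
        Strictly positive values, one per name (units are model-specific).
    reference
        Optional "true" values used by synthetic-data generators.
    """

    names: tuple[str, ...]
    values: np.ndarray
    reference: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or len(names) != values.size:
            raise ValueError("names and values must be 1-D and of equal length")
        if len(set(names)) != len(names):
            raise ValueError(f"parameter names must be unique, got {names}")
        if not np.all(np.isfinite(values)) or np.any(values <= 0.0):
            bad = [n for n, v in zip(names, values) if not (v > 0 and np.isfinite(v))]
            raise ValueError(f"parameter values must be finite and > 0; offending: {bad}")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "values", values)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != values.shape:
                raise ValueError("reference must match values in shape")
            object.__setattr__(self, "reference", ref)

    # -- construction -------------------------------------------------
    @classmethod
    def from_dict(cls, mapping: Mapping[str, float], reference: Mapping[str, float] | None = None) -> "ParameterSet":
        names = tuple(mapping)
        values = np.array([mapping[n] for n in names], dtype=float)
        ref = None
        if reference is not None:
            ref = np.array([reference[n] for n in names], dtype=float)
        return cls(names, values, ref)

    @classmethod
    def from_log(cls, names: Sequence[str], log_values: np.ndarray) -> "ParameterSet":
        return cls(tuple(names), np.exp(np.asarray(log_values, dtype=float)))

    # -- views ---------------------------------------------------------
    @property
    def log_values(self) -> np.ndarray:
        """Elementwise natural log of the values (round-trips via exp)."""
        return np.log(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self.names.index(name)])
        except ValueError:
            raise KeyError(f"no parameter named {name!r}; have {self.names}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)

    # -- derived sets --------------------------------------------------
    def with_values(self, values: np.ndarray) -> "ParameterSet":
        return ParameterSet(self.names, np.asarray(values, dtype=float), self.reference)

    def updated(self, **changes: float) -> "ParameterSet":
        d = self.as_dict()
        for k, v in changes.items():
            if k not in d:
                raise KeyError(f"no parameter named {k!r}")
            d[k] = v
        return ParameterSet(self.names, np.array([d[n] for n in self.names]), self.reference)

    def subset(self, names: Iterable[str]) -> "ParameterSet":
        names = tuple(names)
        idx = [self.names.index(n) for n in names]
        return ParameterSet(names, self.values[idx])

    def drop(self, names: Iterable[str]) -> "ParameterSet":
        drop = set(names)
        missing = drop - set(self.names)
        if missing:
            raise KeyError(f"unknown parameter names {sorted(missing)}")
        keep = tuple(n for n in self.names if n not in drop)
        return self.subset(keep)
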