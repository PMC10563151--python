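"""Marker panels and per-channel measurement transforms.

A panel fixes the channel order shared by every event matrix in a cohort and
carries one transform descriptor per channel.  Fluorescence channels are
conventionally variance-stabilized with arcsinh (cofactor ~150 for ordinary
flow cytometry); scatter channels are min-max scaled to [0, 1] with extrema
fit on the training cohort only, so test samples see the same mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

_KINDS = ("identity", "arcsinh", "minmax")


@dataclass
class TransformSpec:
    """Transform descriptor for one channel.

    kind: "identity", "arcsinh" (x -> asinh(x / cofactor)) or "minmax"
    (x -> (x - vmin) / (vmax - vmin), extrema fit on the training cohort).
    """

    kind: str = "identity"
    cofactor: float = 150.0
    vmin: Optional[float] = None
    vmax: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "arcsinh" and self.cofactor <= 0:
            raise ValueError("arcsinh cofactor must be positive")

    def apply(self, x: np.ndarray, channel: str) -> np.ndarray:
        if self.kind == "identity":
            return np.asarray(x, dtype=float)
        if self.kind == "arcsinh":
            return np.arcsinh(np.asarray(x, dtype=float) / self.cofactor)
        if self.vmin is None or self.vmax is None:
            raise ValueError(
                f"min-max transform for channel {channel!r} has no fitted extrema; "
                "call MarkerPanel.fit_minmax on the training cohort first"
            )
        rng = self.vmax - self.vmin
        if rng <= 0:
            raise ValueError(f"min-max transform for channel {channel!r} has zero range")
        return (np.asarray(x, dtype=float) - self.vmin) / rng

    def invert(self, x: np.ndarray, channel: str) -> np.ndarray:
        if self.kind == "identity":
            return np.asarray(x, dtype=float)
        if self.kind == "arcsinh":
            return np.sinh(np.asarray(x, dtype=float)) * self.cofactor
        if self.vmin is None or self.vmax is None:
            raise ValueError(f"min-max transform for channel {channel!r} has no fitted extrema")
        return np.asarray(x, dtype=float) * (self.vmax - self.vmin) + self.vmin


@dataclass
class MarkerPanel:
    """Ordered channel identifiers plus one transform spec per channel."""

    names: List[str]
    transforms: Dict[str, TransformSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"panel channel names must be unique; duplicated: {dupes}")
        for name in self.names:
            self.transforms.setdefault(name, TransformSpec())
        unknown = set(self.transforms) - set(self.names)
        if unknown:
            raise ValueError(f"transforms given for channels not in panel: {sorted(unknown)}")

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in panel {self.names}") from None

    @classmethod
    def default(cls, names: Sequence[str], scatter_prefixes: Sequence[str] = ("FSC", "SSC")) -> "MarkerPanel":
        """Standard cytometry preprocessing: arcsinh(cofactor 150) for
        fluorescence channels, min-max for scatter channels."""
        transforms = {}
        for n in names:
            if any(n.upper().startswith(p) for p in scatter_prefixes):
                transforms[n] = TransformSpec(kind="minmax")
            else:
                transforms[n] = TransformSpec(kind="arcsinh", cofactor=150.0)
        return cls(names=list(names), transforms=transforms)

    @classmethod
    def identity(cls, names: Sequence[str]) -> "MarkerPanel":
        """Panel whose channels are already in transformed units."""
        return cls(names=list(names), transforms={n: TransformSpec() for n in names})

    def fit_minmax(self, matrices: Sequence[np.ndarray]) -> "MarkerPanel":
        """Fit min-max extrema for every minmax channel on training data.

        Returns a new panel; the receiver is unchanged.
        """
        if not matrices:
            raise ValueError("no matrices given to fit min-max extrema")
        stacked_min = np.min([m.min(axis=0) for m in matrices], axis=0)
        stacked_max = np.max([m.max(axis=0) for m in matrices], axis=0)
        new_transforms = {}
        for d, name in enumerate(self.names):
            spec = self.transforms[name]
            if spec.kind == "minmax":
                if stacked_max[d] - stacked_min[d] <= 0:
                    raise ValueError(f"min-max transform for channel {name!r} has zero range")
                spec = replace(spec, vmin=float(stacked_min[d]), vmax=float(stacked_max[d]))
            new_transforms[name] = spec
        return MarkerPanel(names=list(self.names), transforms=new_transforms)

    def transform_matrix(self, values: np.ndarray) -> np.ndarray:
        """Apply the per-channel transforms columnwise."""
        values = np.asarray(values, dtype=float)
        if values.shape[1] != self.size:
            raise ValueError(f"matrix has {values.shape[1]} columns, panel has {self.size}")
        out = np.empty_like(values)
        for d, name in enumerate(self.names):
            out[:, d] = self.transforms[name].apply(values[:, d], name)
        return out

    def inverse_matrix(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if values.shape[1] != self.size:
            raise ValueError(f"matrix has {values.shape[1]} columns, panel has {self.size}")
        out = np.empty_like(values)
        for d, name in enumerate(self.names):
            out[:, d] = self.transforms[name].invert(values[:, d], name)
        return out

    def inverse_value(self, name: str, x: float) -> float:
        return float(self.transforms[name].invert(np.asarray([x]), name)[0])

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "transforms": {
                n: {
                    "kind": t.kind,
                    "cofactor": t.cofactor,
                    "vmin": t.vmin,
                    "vmax": t.vmax,
                }
                for n, t in self.transforms.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        transforms = {
            n: TransformSpec(
                kind=t.get("kind", "identity"),
                cofactor=t.get("cofactor", 150.0),
                vmin=t.get("vmin"),
                vmax=t.get("vmax"),
            )
            for n, t in d.get("transforms", {}).items()
        }
        return cls(names=list(d["names"]), transforms=transforms)
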