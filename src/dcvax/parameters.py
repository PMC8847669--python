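"""Kinetic parameters and fixed design constants of the DC-vaccination model.

The model has exactly 46 named parameters: 10 for the organ bio-distribution of
injected dendritic cells (6 transfer/efflux rates plus 4 organ volumes), 21 for
the intracellular NF-kB signaling module of the DC (upstream kinases, IKK,
NF-kB/IkBa core), 16 for the NF-kB-driven maturation markers (IL-8, IL-6,
IL-12, CD70) and 5 for the CD8+ T-cell differentiation cascade.  Rates are in
1/h, organ volumes in mm^3, signaling species are non-dimensional, T cells are
counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "PARAM_GROUPS",
    "VOLUME_NAMES",
    "ParameterSet",
    "DesignConstants",
    "reference_parameters",
]

#: Canonical parameter order used for every vectorized interface.
PARAM_GROUPS: dict[str, tuple[str, ...]] = {
    "distribution": (
        "mu_BS", "mu_BLu", "mu_BLi", "mu", "mu_S0", "mu_Lu0",
        "Q_Blood", "Q_Spleen", "Q_Lung", "Q_Liver",
    ),
    "upstream": (
        "k_ph1_TRAF2", "k_ph1_IRAK1", "k_ph2", "k_deg_TRAF2p", "k_deg_IRAK1p",
    ),
    "ikk": ("k_syn_IKK", "k_act_IKK", "k_deg_IKK", "k_deg_IKKb"),
    "nfkb": (
        "N_tot", "k_ass", "k_transc_mIkBa", "k_deg_mIkBa",
        "k_tranl_IkBa", "k_loss_IkBa",
    ),
    "il8": (
        "k_transc1_mIL8", "k_transc2_mIL8", "k_deg_mIL8",
        "k_transl_IL8", "k_deg_IL8", "k_sec_IL8",
    ),
    "il6": ("k_transc2_mIL6", "k_deg_mIL6", "k_transl_IL6", "k_deg_IL6"),
    "il12": ("k_transc2_mIL12", "k_deg_mIL12", "k_transl_IL12", "k_deg_IL12"),
    "cd70": ("k_transc2_CD70", "k_deg_CD70"),
    "tcell": ("k_act_N", "K_4", "k_diff1_EE", "k_diff2_EE", "k_deg_SLE"),
}

PARAM_NAMES: tuple[str, ...] = tuple(
    name for group in PARAM_GROUPS.values() for name in group
)
assert len(PARAM_NAMES) == 46

VOLUME_NAMES: tuple[str, ...] = ("Q_Blood", "Q_Spleen", "Q_Lung", "Q_Liver")

_INDEX: dict[str, int] = {name: i for i, name in enumerate(PARAM_NAMES)}


class ParameterValidationError(ValueError):
    """A parameter set violates its contracts (sign, bounds, completeness)."""


@dataclass(frozen=True)
class DesignConstants:
    """Fixed structural constants that are not among the 46 calibrated parameters.

    Attributes
    ----------
    tau:
        Delay (h) between DC-derived stimulation in the spleen and its effect
        on naive T-cell activation.
    A:
        Clonal amplification factor on the naive -> early-effector conversion.
    delta_IkBa:
        Basal IkBa protein turnover (1/h), keeps the resting NF-kB module from
        freezing when IKKb is absent.
    f_SLE2M:
        Fraction of the short-lived-effector death flux entering the memory
        pool; fixed at 0.1.
    DC_in:
        Number of DCs injected intravenously at t = 0.
    T_0:
        Initial count of antigen-specific naive CD8+ T cells in the spleen.
    """

    tau: float = 24.0
    A: float = 10.0
    delta_IkBa: float = 0.05
    f_SLE2M: float = 0.1
    DC_in: float = 1e5
    T_0: float = 1e6
    horizon_sensitivity: float = 200.0
    horizon_steady: float = 4000.0

    def __post_init__(self) -> None:
        if self.f_SLE2M != 0.1:
            raise ParameterValidationError("f_SLE2M is fixed at 0.1")
        for name in ("tau", "A", "delta_IkBa",
                     "horizon_sensitivity", "horizon_steady"):
            if getattr(self, name) <= 0:
                raise ParameterValidationError(f"{name} must be positive")
        if self.DC_in < 0 or self.T_0 < 0:
            raise ParameterValidationError("cell counts must be >= 0")


@dataclass
class ParameterSet:
    """The 46 named kinetic constants/volumes/totals with bounds and units.

    ``values`` maps every name in :data:`PARAM_NAMES` to a non-negative float.
    ``lower``/``upper`` carry calibration bounds, ``fixed`` marks parameters
    excluded from estimation (the organ volumes are always fixed).
    """

    values: dict[str, float]
    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    fixed: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.values)
        extra = set(self.values) - set(PARAM_NAMES)
        if missing:
            raise ParameterValidationError(f"missing parameters: {sorted(missing)}")
        if extra:
            raise ParameterValidationError(f"unknown parameters: {sorted(extra)}")
        for name, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ParameterValidationError(f"{name} must be finite and >= 0")
        for name in VOLUME_NAMES:
            if self.values[name] <= 0:
                raise ParameterValidationError(f"volume {name} must be > 0")
        for name in set(self.lower) & set(self.upper):
            if self.lower[name] > self.upper[name]:
                raise ParameterValidationError(f"bounds crossed for {name}")
        self.fixed = set(self.fixed) | set(VOLUME_NAMES)

    # -- access ----------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self) -> np.ndarray:
        """Values in canonical :data:`PARAM_NAMES` order, shape (46,)."""
        return np.array([self.values[n] for n in PARAM_NAMES], float)

    @staticmethod
    def index(name: str) -> int:
        return _INDEX[name]

    @classmethod
    def from_array(cls, vec: Iterable[float], template: "ParameterSet | None" = None
                   ) -> "ParameterSet":
        vec = np.asarray(list(vec), float)
        if vec.shape != (46,):
            raise ParameterValidationError(f"expected 46 values, got {vec.shape}")
        values = dict(zip(PARAM_NAMES, vec.tolist()))
        if template is None:
            return cls(values=values)
        return cls(values=values, lower=dict(template.lower),
                   upper=dict(template.upper), units=dict(template.units),
                   fixed=set(template.fixed))

    def with_overrides(self, overrides: Mapping[str, float]) -> "ParameterSet":
        for name in overrides:
            if name not in _INDEX:
                raise ParameterValidationError(f"unknown parameter {name!r}")
        values = dict(self.values)
        values.update({k: float(v) for k, v in overrides.items()})
        return replace(self, values=values)

    def free_names(self) -> list[str]:
        return [n for n in PARAM_NAMES if n not in self.fixed]

    # -- IO --------------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            name: {
                "value": self.values[name],
                "lower": self.lower.get(name),
                "upper": self.upper.get(name),
                "unit": self.units.get(name, ""),
                "fixed": name in self.fixed,
            }
            for name in PARAM_NAMES
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: Mapping[str, Mapping]) -> "ParameterSet":
        values, lower, upper, units, fixed = {}, {}, {}, {}, set()
        for name, entry in payload.items():
            values[name] = float(entry["value"])
            if entry.get("lower") is not None:
                lower[name] = float(entry["lower"])
            if entry.get("upper") is not None:
                upper[name] = float(entry["upper"])
            if entry.get("unit"):
                units[name] = str(entry["unit"])
            if entry.get("fixed"):
                fixed.add(name)
        return cls(values=values, lower=lower, upper=upper, units=units, fixed=fixed)


def reference_parameters() -> ParameterSet:
    """The shipped reference parameterization (versioned package fixture)."""
    text = resources.files("dcvax.data").joinpath("reference_parameters.json").read_text()
    return ParameterSet._from_payload(json.loads(text))
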