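"""Synthetic calibration datasets.

Emulates the four experimental datasets the model is calibrated against,
with their statistical structure, so the whole pipeline is testable without
the original figures:

``biodistribution``
    Radioactivity-derived DC counts in blood, lung, liver and spleen over
    72 h after intravenous injection (triplicate quantification;
    multiplicative noise).
``nfkb``
    Max-normalized NF-kB DNA-binding activity plus IkBa mRNA (qPCR) and
    protein (western blot) after LPS stimulation (additive noise on the
    normalized scale).
``cytokine``
    IL-12, IL-6, IL-8 and CD70 levels 4-72 h after caIKK electroporation,
    mean +/- sd over 4 replicates.
``tcell``
    Short-lived effector T-cell counts under three weekly DC stimulations,
    mock vs caIKK arms.

Values are sampled from the reference model under each kind's scenario and
noised; with the noise switched off the dataset reproduces the reference
trajectory exactly, which closes the loop with the calibration cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Trajectory, builtin_scenarios, simulate
from .parameters import DesignConstants, ParameterSet

__all__ = ["Dataset", "GeneratorConfig", "generate_dataset", "KINDS",
           "kind_observables"]

KINDS = ("biodistribution", "nfkb", "cytokine", "tcell")

#: kind -> (scenario per arm, [(observable id, trajectory variable)], max-normalized?)
_KIND_SPEC: dict[str, dict] = {
    "biodistribution": {
        "arms": {"iv": "normal_dc"},
        "observables": [("dc_blood", "dc_blood_count"),
                        ("dc_lung", "dc_lung_count"),
                        ("dc_liver", "dc_liver_count"),
                        ("dc_spleen", "dc_spleen_count")],
        "max_normalized": False,
        "times": (0.5, 1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0),
        # triplicate quantification so the sd-weighted cost is defined
        "replicates": 3,
    },
    "nfkb": {
        "arms": {"lps": "lps"},
        "observables": [("nfkb_activity", "nfkb"),
                        ("ikba_mrna", "m_ikba"),
                        ("ikba_protein", "ikba")],
        "max_normalized": True,
        "times": (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0),
        "replicates": 3,
    },
    "cytokine": {
        "arms": {"caikk": "caikk_dc"},
        "observables": [("il12", "il12"), ("il6", "il6"),
                        ("il8", "il8"), ("cd70", "cd70")],
        "max_normalized": False,
        "times": (4.0, 24.0, 48.0, 72.0),
        "replicates": 4,
    },
    "tcell": {
        "arms": {"mock": "tcell_invitro_normal", "caikk": "tcell_invitro_caikk"},
        "observables": [("sle_count", "short_lived_effector")],
        "max_normalized": False,
        "times": (168.0, 336.0, 504.0),
        "replicates": 3,
    },
}


def kind_observables(kind: str) -> list[str]:
    return [o for o, _ in _KIND_SPEC[kind]["observables"]]


@dataclass
class Dataset:
    """Time-stamped observations with uncertainty and normalization metadata."""

    kind: str
    frame: pd.DataFrame          # observable, arm, time_h, value, sd, n
    max_normalized: bool
    reference_max: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"observable", "arm", "time_h", "value", "sd", "n"}
        if not required <= set(self.frame.columns):
            raise ValueError(f"dataset frame needs columns {sorted(required)}")
        f = self.frame
        if (f["time_h"] < 0).any():
            raise ValueError("times must be non-negative")
        if (f["sd"].fillna(0.0) < 0).any():
            raise ValueError("sd must be >= 0")
        if (f["n"] < 1).any():
            raise ValueError("replicate count must be >= 1")
        if self.max_normalized:
            for obs, g in f.groupby("observable"):
                if not np.isclose(g["value"].max(), 1.0, atol=1e-9):
                    raise ValueError(f"max-normalized observable {obs!r} has "
                                     f"max {g['value'].max()!r}, expected 1")

    def to_csv(self, path) -> None:
        meta = f"# kind={self.kind} max_normalized={int(self.max_normalized)}\n"
        with open(path, "w") as fh:
            fh.write(meta)
            self.frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Dataset":
        with open(path) as fh:
            header = fh.readline().strip()
            frame = pd.read_csv(fh)
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        return cls(kind=meta["kind"], frame=frame,
                   max_normalized=bool(int(meta["max_normalized"])))


@dataclass
class GeneratorConfig:
    """Noise model and sampling design of the synthetic generator.

    The defaults are the study conditions: multiplicative lognormal noise
    (sigma = 0.1) for counts and concentrations, additive Gaussian noise
    (sd = 0.05) for max-normalized signals, and per-kind sampling times and
    replicate counts matching the source assays.
    """

    params: ParameterSet
    constants: DesignConstants = field(default_factory=DesignConstants)
    lognormal_sigma: float = 0.1
    gaussian_sd: float = 0.05
    times: Mapping[str, Sequence[float]] | None = None
    replicates: Mapping[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lognormal_sigma < 0 or self.gaussian_sd < 0:
            raise ValueError("noise levels must be >= 0")

    def times_for(self, kind: str) -> np.ndarray:
        times = (self.times or {}).get(kind, _KIND_SPEC[kind]["times"])
        return np.asarray(times, float)

    def replicates_for(self, kind: str) -> int:
        return int((self.replicates or {}).get(
            kind, _KIND_SPEC[kind]["replicates"]))


def _simulate_kind(kind: str, arm_scenario: str, times: np.ndarray,
                   config: GeneratorConfig) -> Trajectory:
    scen = builtin_scenarios()[arm_scenario]
    t_end = float(times.max())
    grid = np.union1d(np.linspace(0.0, t_end, 801), times)
    # tight tolerances: these values serve as ground truth for the noiseless
    # closure with the (partly closed-form) calibration predictions
    return simulate(scen, config.params, config.constants, grid=grid,
                    rtol=1e-9, atol=1e-12)


def generate_dataset(kind: str, config: GeneratorConfig) -> Dataset:
    """Simulate the reference model for a dataset kind and add noise.

    With both noise levels 0 the emitted values equal the reference
    trajectory at the sampled times (identity contract); a fixed seed gives
    byte-identical output.
    """
    if kind not in _KIND_SPEC:
        raise KeyError(f"unknown dataset kind {kind!r}; choose from {KINDS}")
    spec = _KIND_SPEC[kind]
    times = config.times_for(kind)
    n_rep = config.replicates_for(kind)
    rng = np.random.default_rng(config.seed)

    rows = []
    for arm, scenario_name in spec["arms"].items():
        traj = _simulate_kind(kind, scenario_name, times, config)
        for obs, var in spec["observables"]:
            truth = np.interp(times, traj.time, traj[var])
            if not np.all(np.isfinite(truth)):
                raise FloatingPointError(
                    f"non-finite simulated values for {obs!r}")
            if spec["max_normalized"]:
                scale = float(np.max(truth))
                if scale <= 0:
                    raise ValueError(f"cannot max-normalize {obs!r}: max <= 0")
                truth = truth / scale
                reps = truth[None, :] + rng.normal(
                    0.0, config.gaussian_sd, (n_rep, times.size))
                reps = np.clip(reps, 0.0, None)
            else:
                reps = truth[None, :] * rng.lognormal(
                    0.0, config.lognormal_sigma, (n_rep, times.size)) \
                    if config.lognormal_sigma > 0 else np.tile(truth, (n_rep, 1))
            value = reps.mean(axis=0)
            sd = reps.std(axis=0, ddof=1) if n_rep > 1 else np.full(times.size, np.nan)
            if spec["max_normalized"]:
                # renormalize so the reported maximum is exactly 1
                value = value / value.max()
            for j, t in enumerate(times):
                rows.append((obs, arm, float(t), float(value[j]),
                             float(sd[j]) if np.isfinite(sd[j]) else np.nan,
                             n_rep))
    frame = pd.DataFrame(rows, columns=["observable", "arm", "time_h",
                                        "value", "sd", "n"])
    ref_max = {obs: float(frame.loc[frame.observable == obs, "value"].max())
               for obs in frame.observable.unique()}
    return Dataset(kind=kind, frame=frame,
                   max_normalized=spec["max_normalized"],
                   reference_max=ref_max)
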