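"""Scenario catalogue and synthetic inputs.

Every experiment of the study is available as a named, fully serializable
``Scenario``: steady pacing for each mutation condition and transmural cell
type, restitution scans, transmural-cable conduction runs, ring reentry and
closed-loop pump runs.  Reduced-duration variants (``<name>-reduced``) exist
for quick turnaround; the full variants match the study protocol durations.

``SyntheticCaTransient`` generates idealized periodic calcium transients so
the myofilament stage can be tested in isolation from the ionic model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .ionic_cell import CELL_TYPES, CONDITIONS

PROTOCOLS = ("pacing", "restitution", "cable", "reentry", "pump")


@dataclass
class Scenario:
    """One fully specified experiment configuration."""

    name: str
    condition: str
    protocol: str
    cell_type: str | None = None      # pacing scenarios
    params: dict = field(default_factory=dict)
    seed: int = 0
    reduced: bool = False

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.protocol not in PROTOCOLS:
            raise ConfigurationError(f"unknown protocol {self.protocol!r}")
        if self.cell_type is not None and self.cell_type not in CELL_TYPES:
            raise ConfigurationError(f"unknown cell type {self.cell_type!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(**d)

    def to_yaml(self) -> str:
        import yaml
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Scenario":
        import yaml
        return cls.from_dict(yaml.safe_load(text))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _catalogue() -> dict:
    cat = {}
    for cond in CONDITIONS:
        for ct in CELL_TYPES:
            cat[f"sinus-{cond}-{ct}"] = Scenario(
                name=f"sinus-{cond}-{ct}", condition=cond, protocol="pacing",
                cell_type=ct,
                params={"BCL": 600.0, "n_beats": 50, "dt": 0.02})
        cat[f"restitution-{cond}"] = Scenario(
            name=f"restitution-{cond}", condition=cond,
            protocol="restitution",
            params={"BCL_start": 400.0, "BCL_stop": 200.0, "BCL_step": 10.0,
                    "beats_per_BCL": 30, "measured_beats": 8,
                    "cell_types": list(CELL_TYPES)})
        cat[f"cable-{cond}"] = Scenario(
            name=f"cable-{cond}", condition=cond, protocol="cable",
            params={"length": 1.5, "dx": 0.025, "duration": 600.0,
                    "target_cv": 70.0})
        cat[f"reentry-{cond}"] = Scenario(
            name=f"reentry-{cond}", condition=cond, protocol="reentry",
            params={"circumference": 25.0, "dx": 0.025, "duration": 10000.0,
                    "target_cv": 70.0})
        cat[f"pump-{cond}"] = Scenario(
            name=f"pump-{cond}", condition=cond, protocol="pump",
            params={"BCL": 600.0, "n_beats": 25})
    # reduced-duration variants for quick runs
    reductions = {"pacing": {"n_beats": 30},
                  "restitution": {"BCL_start": 400.0, "BCL_stop": 240.0,
                                  "beats_per_BCL": 20, "measured_beats": 6},
                  "cable": {},
                  "reentry": {"duration": 2500.0},
                  "pump": {"n_beats": 12}}
    for name, sc in list(cat.items()):
        p = dict(sc.params)
        p.update(reductions[sc.protocol])
        cat[f"{name}-reduced"] = Scenario(
            name=f"{name}-reduced", condition=sc.condition,
            protocol=sc.protocol, cell_type=sc.cell_type, params=p,
            reduced=True)
    return cat


_CATALOGUE = _catalogue()


def list_scenarios(include_reduced: bool = True) -> list[str]:
    return [n for n in sorted(_CATALOGUE)
            if include_reduced or not _CATALOGUE[n].reduced]


def make_scenario(name: str) -> Scenario:
    """Look up a catalogue scenario by name (a fresh copy)."""
    if name not in _CATALOGUE:
        raise ConfigurationError(
            f"unknown scenario {name!r}; valid names:\n  " +
            "\n  ".join(list_scenarios()))
    sc = _CATALOGUE[name]
    return Scenario.from_dict(sc.to_dict())


# ---------------------------------------------------------------------------
# Synthetic calcium transients
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCaTransient:
    """Idealized periodic calcium transient (double-exponential pulse)."""

    baseline: float = 0.0001      # mM
    amplitude: float = 0.001      # mM
    time_to_peak: float = 30.0    # ms
    tau_decay: float = 60.0       # ms
    period: float = 600.0         # ms

    def __post_init__(self):
        if self.baseline <= 0:
            raise ConfigurationError("baseline must be positive")
        if self.amplitude < 0:
            raise ConfigurationError("amplitude must be non-negative")
        if self.time_to_peak <= 0 or self.tau_decay <= 0 or self.period <= 0:
            raise ConfigurationError("time parameters must be positive")
        if self.time_to_peak >= self.period:
            raise ConfigurationError("time_to_peak must be below the period")
        if self.time_to_peak >= self.tau_decay:
            # the rise/decay double-exponential cannot peak later than its
            # decay constant
            raise ConfigurationError(
                "time_to_peak must be below tau_decay for a "
                "double-exponential transient")


def _rise_tau_for_peak(tp: float, tau_d: float) -> float:
    """Rise time constant such that exp(-t/tau_d) - exp(-t/tau_r) peaks
    at t = tp (bisection; the peak time is monotone in tau_r)."""
    lo, hi = 1e-6, tau_d * 0.999999

    def peak_time(tau_r):
        return np.log(tau_d / tau_r) / (1.0 / tau_r - 1.0 / tau_d)

    if peak_time(hi) < tp:   # tp unreachable below tau_d; clamp
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if peak_time(mid) < tp:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def synthetic_ca(params: SyntheticCaTransient, t: np.ndarray) -> np.ndarray:
    """Evaluate the periodic transient on a time grid (ms -> mM)."""
    t = np.asarray(t, float)
    if params.amplitude == 0.0:
        return np.full_like(t, params.baseline)
    tau_d = params.tau_decay
    tau_r = _rise_tau_for_peak(params.time_to_peak, tau_d)
    tau = np.mod(t, params.period)
    shape = np.exp(-tau / tau_d) - np.exp(-tau / tau_r)
    peak = (np.exp(-params.time_to_peak / tau_d) -
            np.exp(-params.time_to_peak / tau_r))
    return params.baseline + params.amplitude * shape / peak
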