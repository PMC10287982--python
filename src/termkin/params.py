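"""Kinetic parameter containers and bundled literature fixtures.

The two central containers mirror the measured rate constants of bacterial
translation termination:

``SchemeRates``
    class-I release factor (RF1/RF2) constants of the first-bound/rebound
    termination scheme: association to the pre-termination ribosome
    (``k_ion``), RF3-independent activation (``k_iIA``), spontaneous
    (``k_iAR_minus``) and RF3-accelerated (``k_iAR_plus``) intersubunit
    rotation, post-rotation class-I RF dissociation (``k_iRD_plus``), and the
    RF3 equilibrium dissociation constant ``K3``.

``RF3Kinetics``
    class-II release factor (RF3) constants measured with dye-labelled RF3:
    bimolecular association ``k_3on``, the sampling-mode dissociation rate
    mixture ``k_3off`` (rate, amplitude pairs), RF3-bound rotation ``k_3BR``
    and post-class-I-RF RF3 departure ``k_31D``, per guanine nucleotide.

Fixtures for the published parameter sets ship as JSON under
``termkin/data`` and load through :func:`load_scheme_rates` /
:func:`load_rf3_kinetics`.  Units: seconds, per second, per (uM * s), uM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

__all__ = [
    "SchemeRates",
    "RF3Kinetics",
    "MeanTimes",
    "load_scheme_rates",
    "load_rf3_kinetics",
    "fixture_path",
]

_AMP_TOL = 1e-9


def _require_positive(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) or value == math.inf):
        raise ValueError(f"{name} must be a finite positive number, got {value!r}")
    if value <= 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class SchemeRates:
    """Class-I release factor rate constants of the termination scheme.

    ``k_iIA`` may be ``math.inf`` for the rebound scheme, where the ribosome
    is already activated at time zero and the activation step contributes no
    time.
    """

    rf_id: str                 # "RF1" or "RF2"
    temperature: float         # degrees C
    k_ion: float               # uM^-1 s^-1, class-I RF association
    k_iIA: float               # s^-1, RF3-independent activation
    k_iAR_minus: float         # s^-1, rotation without RF3
    k_iAR_plus: float          # s^-1, rotation with RF3 bound
    k_iRD_plus: float          # s^-1, post-rotation class-I RF dissociation
    K3: float                  # uM, RF3 equilibrium dissociation constant

    def __post_init__(self) -> None:
        if self.rf_id not in ("RF1", "RF2"):
            raise ValueError(f"rf_id must be 'RF1' or 'RF2', got {self.rf_id!r}")
        for name in ("k_ion", "k_iAR_minus", "k_iAR_plus", "k_iRD_plus", "K3"):
            _require_positive(name, getattr(self, name))
        if self.k_iIA != math.inf:
            _require_positive("k_iIA", self.k_iIA)


@dataclass(frozen=True)
class RF3Kinetics:
    """RF3 binding/dissociation constants for one guanine nucleotide.

    ``k_3off`` is a mixture of sampling-state dissociation rates with
    amplitudes summing to one; ``k_3BR``/``k_31D``/``k_1RD_plus`` are None
    for nucleotides that support no productive (rotation-coupled) binding,
    i.e. GDP.
    """

    nucleotide: str                                  # GTP, GDP, GDPCP, mixture
    k_3on: float                                     # uM^-1 s^-1
    k_3off: tuple[tuple[float, float], ...]          # (rate s^-1, amplitude)
    k_3BR: Optional[float] = None                    # s^-1, RF3-bound rotation
    k_31D: Optional[float] = None                    # s^-1, post-RF1 RF3 departure
    k_1RD_plus: Optional[float] = None               # s^-1, RF1 departure after rotation

    def __post_init__(self) -> None:
        if self.nucleotide not in ("GTP", "GDP", "GDPCP", "mixture"):
            raise ValueError(f"unknown nucleotide {self.nucleotide!r}")
        if not 1 <= len(self.k_3off) <= 3:
            raise ValueError("k_3off must have 1-3 (rate, amplitude) entries")
        _require_positive("k_3on", self.k_3on)
        total = 0.0
        for rate, amp in self.k_3off:
            _require_positive("k_3off rate", rate)
            if not 0 < amp <= 1:
                raise ValueError(f"k_3off amplitude out of (0, 1]: {amp}")
            total += amp
        if abs(total - 1.0) > _AMP_TOL:
            raise ValueError(f"k_3off amplitudes must sum to 1, got {total}")
        for name in ("k_3BR", "k_31D", "k_1RD_plus"):
            value = getattr(self, name)
            if value is not None:
                _require_positive(name, value)

    @property
    def supports_rotation(self) -> bool:
        """Whether productive (rotation-coupled) RF3 binding can occur."""
        return self.k_3BR is not None

    @property
    def mean_sampling_dwell(self) -> float:
        """Mean sampling occupancy, sum of amplitude/rate over the mixture."""
        return sum(amp / rate for rate, amp in self.k_3off)


@dataclass(frozen=True)
class MeanTimes:
    """Mean dwell decomposition at one RF3 concentration.

    ``tau_iBD = tau_iBR + tau_iRD`` holds exactly by construction.
    """

    tau_iBR: float   # s, class-I RF binding -> intersubunit rotation
    tau_iRD: float   # s, rotation -> class-I RF dissociation
    rf3_conc: float  # uM
    mode: str        # "first_bound" or "rebound"

    def __post_init__(self) -> None:
        if self.mode not in ("first_bound", "rebound"):
            raise ValueError(f"mode must be first_bound or rebound, got {self.mode!r}")
        if self.tau_iBR < 0 or self.tau_iRD < 0 or self.rf3_conc < 0:
            raise ValueError("times and concentration must be non-negative")

    @property
    def tau_iBD(self) -> float:
        return self.tau_iBR + self.tau_iRD


_TABLE1_FILES = {
    ("RF1", 20): "table1_rf1_20c.json",
    ("RF1", 30): "table1_rf1_30c.json",
    ("RF2", 20): "table1_rf2_20c.json",
}
_TABLE2_FILES = {
    "GTP": "table2_gtp.json",
    "GDP": "table2_gdp.json",
    "GDPCP": "table2_gdpcp.json",
}


def fixture_path(name: str):
    """Importlib handle for a bundled fixture file (context-manager free read)."""
    return resources.files("termkin.data").joinpath(name)


def _load_json(name: str) -> dict:
    return json.loads(fixture_path(name).read_text())


def load_scheme_rates(rf_id: str = "RF1", temperature: float = 20) -> SchemeRates:
    """Load a published class-I RF parameter set.

    Available: RF1 at 20 or 30 C, RF2 at 20 C.
    """
    try:
        raw = _load_json(_TABLE1_FILES[(rf_id, int(temperature))])
    except KeyError:
        raise KeyError(f"no fixture for {rf_id} at {temperature} C") from None
    return SchemeRates(
        rf_id=raw["rf_id"],
        temperature=raw["temperature_C"],
        k_ion=raw["k_ion"]["estimate"],
        k_iIA=raw["k_iIA"]["estimate"],
        k_iAR_minus=raw["k_iAR_minus"]["estimate"],
        k_iAR_plus=raw["k_iAR_plus"]["estimate"],
        k_iRD_plus=raw["k_iRD_plus"]["estimate"],
        K3=raw["K3"]["estimate"],
    )


def load_rf3_kinetics(nucleotide: str = "GTP") -> RF3Kinetics:
    """Load a published RF3 parameter set (GTP, GDP, or GDPCP)."""
    try:
        raw = _load_json(_TABLE2_FILES[nucleotide])
    except KeyError:
        raise KeyError(f"no fixture for nucleotide {nucleotide!r}") from None

    def _opt(key: str) -> Optional[float]:
        entry = raw.get(key)
        return None if entry is None else entry["estimate"]

    return RF3Kinetics(
        nucleotide=raw["nucleotide"],
        k_3on=raw["k_3on"]["estimate"],
        k_3off=tuple((c["rate"], c["amplitude"]) for c in raw["k_3off"]),
        k_3BR=_opt("k_3BR"),
        k_31D=_opt("k_31D"),
        k_1RD_plus=_opt("k_1RD_plus"),
    )
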