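"""Nuclear-spin constants and thermal (Boltzmann) polarization.

The acquisition planner rescales a measured reference SNR by the ratio of
target to reference polarization.  For thermally polarized samples that
polarization follows from the Larmor frequency and the Boltzmann
distribution; this module supplies both, plus a small user-extensible
registry of gyromagnetic ratios.

Notes
-----
Gyromagnetic ratios are stored as magnitudes of gamma/2pi in MHz/T (gamma of
e.g. 15N is physically negative, but only ratios of polarizations and
frequencies enter the planning equations, so the sign is irrelevant here).
The spin-1/2 two-level formula ``P = tanh(h f / (2 kB T))`` is applied to all
registered nuclei, including the spin-1 deuteron: reference polarizations are
carried as explicit measured/stored values throughout the package, and in the
linear (high-temperature) regime the P ratios used by the planner are
identical between the two-level and Brillouin forms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from scipy.constants import h as _PLANCK, k as _BOLTZMANN

from .errors import InvalidInputError

__all__ = [
    "Nucleus",
    "get_nucleus",
    "register_nucleus",
    "registry_to_json",
    "registry_from_json",
    "larmor_frequency",
    "thermal_polarization",
    "DEFAULT_TEMPERATURE_K",
]

#: Room temperature assumed when a thermal reference states no temperature.
DEFAULT_TEMPERATURE_K = 298.0


@dataclass(frozen=True)
class Nucleus:
    """An NMR-active nucleus.

    Parameters
    ----------
    name : str
        Conventional isotope label, e.g. ``"13C"``.
    gyromagnetic_ratio : float
        ``|gamma / 2 pi|`` in MHz/T.
    spins_per_molecule : int
        Number of equivalent spins of this isotope per molecule of the
        sample; converts molecular to spin concentration (e.g. 2 for the
        protons of H2O).
    """

    name: str
    gyromagnetic_ratio: float
    spins_per_molecule: int = 1

    def __post_init__(self):
        if self.gyromagnetic_ratio <= 0:
            raise InvalidInputError("gyromagnetic_ratio must be > 0 (MHz/T)")
        if self.spins_per_molecule < 1:
            raise InvalidInputError("spins_per_molecule must be >= 1")


# CODATA-2018 / IAEA recommended |gamma/2pi| values, MHz per tesla.
_REGISTRY: dict[str, Nucleus] = {
    "1H": Nucleus("1H", 42.577478461),
    "2H": Nucleus("2H", 6.535902311),
    "13C": Nucleus("13C", 10.7083967),
    "15N": Nucleus("15N", 4.3172671),
    "19F": Nucleus("19F", 40.0775701),
}


def get_nucleus(name: str) -> Nucleus:
    """Look up a nucleus by isotope label (case-sensitive, e.g. ``"13C"``)."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown nucleus {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def register_nucleus(nucleus: Nucleus, *, overwrite: bool = False) -> None:
    """Add a nucleus to the registry.

    Raises :class:`InvalidInputError` if the name is already registered and
    ``overwrite`` is false (names are unique within the registry).
    """
    if nucleus.name in _REGISTRY and not overwrite:
        raise InvalidInputError(f"nucleus {nucleus.name!r} already registered")
    _REGISTRY[nucleus.name] = nucleus


def registry_to_json() -> str:
    """Serialize the registry as JSON (name, gamma_MHz_per_T, spins_per_molecule)."""
    return json.dumps(
        [
            {
                "name": n.name,
                "gamma_MHz_per_T": n.gyromagnetic_ratio,
                "spins_per_molecule": n.spins_per_molecule,
            }
            for n in _REGISTRY.values()
        ],
        indent=2,
        sort_keys=True,
    )


def registry_from_json(text: str, *, overwrite: bool = False) -> list[Nucleus]:
    """Register nuclei from a JSON document produced by :func:`registry_to_json`."""
    loaded = []
    for entry in json.loads(text):
        nuc = Nucleus(
            entry["name"],
            entry["gamma_MHz_per_T"],
            int(entry.get("spins_per_molecule", 1)),
        )
        register_nucleus(nuc, overwrite=overwrite)
        loaded.append(nuc)
    return loaded


def larmor_frequency(nucleus: Nucleus, field: float) -> float:
    """Larmor frequency ``|gamma/2pi| * B0`` in MHz for a field in tesla."""
    if field < 0:
        raise InvalidInputError("field must be >= 0 T")
    return nucleus.gyromagnetic_ratio * field


def thermal_polarization(
    nucleus: Nucleus, field: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Thermal-equilibrium polarization fraction of a spin-1/2 nucleus.

    ``P = tanh(h * f_Larmor / (2 kB T))`` — about 3e-5 for 1H at 9.4 T and
    room temperature.  Monotone increasing in field, decreasing in
    temperature; returns 0 at zero field.
    """
    if temperature <= 0:
        raise InvalidInputError("temperature must be > 0 K")
    f_hz = larmor_frequency(nucleus, field) * 1e6
    return math.tanh(_PLANCK * f_hz / (2.0 * _BOLTZMANN * temperature))
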