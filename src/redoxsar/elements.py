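"""Per-element atomic properties used as descriptor weighting schemes.

Four properties are supported, each also in carbon-scaled form (value
divided by the carbon value), which is the conventional weighting for
autocorrelation and 3D-MoRSE descriptors:

``m``
    relative atomic mass,
``v``
    van der Waals volume (A^3) from the atomic-volume table conventional
    in descriptor software (intersection-corrected, not bare Bondi
    spheres),
``e``
    Sanderson electronegativity,
``p``
    atomic polarizability (10^-24 cm^3).

The unit scheme ``u`` (all weights 1) is handled by the callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: atomic van der Waals volumes (A^3); the table standard in descriptor
#: calculators, which corrects sphere volumes for bonded overlap.
VDW_VOLUME = {
    "H": 6.709, "C": 22.449, "N": 15.599, "O": 11.494, "F": 9.203,
    "P": 24.429, "S": 24.429, "Cl": 23.450, "Br": 31.060, "I": 38.730,
}

SANDERSON_EN = {
    "H": 2.592, "C": 2.746, "N": 3.194, "O": 3.654, "F": 4.000,
    "P": 2.515, "S": 2.957, "Cl": 3.475, "Br": 3.219, "I": 2.778,
}

POLARIZABILITY = {
    "H": 0.667, "C": 1.760, "N": 1.100, "O": 0.802, "F": 0.557,
    "P": 3.630, "S": 2.900, "Cl": 2.180, "Br": 3.050, "I": 5.350,
}

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}


@dataclass(frozen=True)
class AtomPropertyTable:
    """Element -> property lookup with carbon-scaled companions.

    ``scaled(scheme, element)`` returns value/value_C, so carbon is 1 for
    every scheme by construction.
    """

    mass: dict = field(default_factory=lambda: dict(ATOMIC_MASS))
    volume: dict = field(default_factory=lambda: dict(VDW_VOLUME))
    electronegativity: dict = field(default_factory=lambda: dict(SANDERSON_EN))
    polarizability: dict = field(default_factory=lambda: dict(POLARIZABILITY))

    _SCHEMES = {"m": "mass", "v": "volume", "e": "electronegativity", "p": "polarizability"}

    def raw(self, scheme: str, element: str) -> float:
        if scheme not in self._SCHEMES:
            raise KeyError(f"unknown weighting scheme {scheme!r}; expected one of m, v, e, p")
        table = getattr(self, self._SCHEMES[scheme])
        try:
            return table[element]
        except KeyError:
            raise KeyError(f"no {self._SCHEMES[scheme]} tabulated for element {element!r}") from None

    def scaled(self, scheme: str, element: str) -> float:
        """Carbon-scaled property value (value / value for carbon)."""
        return self.raw(scheme, element) / self.raw(scheme, "C")

    def weights(self, scheme: str, elements: list[str]) -> list[float]:
        """Carbon-scaled weights for a sequence of element symbols.

        ``scheme='u'`` gives unit weights.
        """
        if scheme == "u":
            return [1.0] * len(elements)
        return [self.scaled(scheme, el) for el in elements]


DEFAULT_PROPERTIES = AtomPropertyTable()
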