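"""Archetype geometry presets and cover -> frontal-area-index relationships.

Three archetypal colony forms span the geometric range of reef benthos:
"table" (a plate on a stem, large plan area but small frontal area),
"massive" (a monolithic mound) and "branching" (an array of thin vertical
elements whose branches all add frontal area).  The bundled presets carry
the measured geometry (height, plan area and azimuth-resolved frontal area)
of one digitised colony of each form, in centimetres.

Because each colony of plan area Ap claims a reef area Ap / cover, the
frontal area index scales linearly with cover:

    lambda_f = cover * Af / Ap.

Porosity is never bundled with the presets: it must be supplied by the user
for lambda_f / phi curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "ArchetypePreset",
    "ARCHETYPES",
    "get_preset",
    "lambda_f_from_cover",
    "lambda_phi_curve",
]


@dataclass(frozen=True)
class ArchetypePreset:
    """Measured geometry of one archetypal colony (centimetre units)."""

    name: str
    species_label: str
    h_cm: float
    Ap_cm2: float
    Af_cm2_by_theta: dict[float, float]

    @property
    def h_m(self) -> float:
        return self.h_cm / 100.0

    def Af_cm2(self, theta: float = 0.0) -> float:
        """Frontal area at a tabulated azimuth; only the massive form has
        entries beyond 0 degrees."""
        key = float(theta)
        if key not in self.Af_cm2_by_theta:
            raise LookupError(
                f"{self.name!r} preset has no frontal area at theta={theta} deg "
                f"(tabulated: {sorted(self.Af_cm2_by_theta)})"
            )
        return self.Af_cm2_by_theta[key]


def _load_presets() -> dict[str, ArchetypePreset]:
    raw = json.loads(
        resources.files("reefflow.data").joinpath("archetype_presets.json").read_text()
    )
    return {
        name: ArchetypePreset(
            name=name,
            species_label=entry["species_label"],
            h_cm=entry["h_cm"],
            Ap_cm2=entry["Ap_cm2"],
            Af_cm2_by_theta={float(t): a for t, a in entry["Af_cm2_by_theta"].items()},
        )
        for name, entry in raw.items()
    }


ARCHETYPES: dict[str, ArchetypePreset] = _load_presets()


def get_preset(name: str) -> ArchetypePreset:
    """Look up a bundled archetype preset by name (table, massive, branching)."""
    try:
        return ARCHETYPES[name]
    except KeyError:
        raise KeyError(
            f"unknown archetype {name!r}; expected one of {sorted(ARCHETYPES)}"
        ) from None


def lambda_f_from_cover(cover: float, Af: float, Ap: float) -> float:
    """Frontal area index lambda_f = cover * Af / Ap.

    ``Af`` and ``Ap`` must share units (the ratio is dimensionless); cover is
    the plan-area fraction occupied by colonies, in (0, 1].
    """
    if not 0.0 < cover <= 1.0:
        raise ValueError("cover must lie in (0, 1]")
    if Ap <= 0:
        raise ValueError("Ap must be positive")
    if Af < 0:
        raise ValueError("Af must be non-negative")
    return cover * Af / Ap


def lambda_phi_curve(
    preset: ArchetypePreset,
    phi: float,
    covers: Sequence[float] | Iterable[float],
    theta: float = 0.0,
) -> list[tuple[float, float]]:
    """Allometric curve (cover, lambda_f / phi) for one archetype.

    lambda_f / phi is the geometry-and-cover part of the attenuation
    predictor alpha; at equal cover and porosity the branching form dominates
    the massive form, which dominates the table form.
    """
    if not 0.0 < phi <= 1.0:
        raise ValueError("phi must lie in (0, 1]")
    af = preset.Af_cm2(theta)
    out = []
    for cover in covers:
        lam = 0.0 if cover == 0 else lambda_f_from_cover(cover, af, preset.Ap_cm2)
        out.append((float(cover), lam / phi))
    return out
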