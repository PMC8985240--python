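"""BOILED-Egg classification of gut absorption and BBB permeation.

The model places each molecule in the (TPSA, WLOGP) plane and tests
membership in two ellipses: the *white* (high passive gastrointestinal
absorption) and the *yolk* (blood-brain-barrier permeation).  The two
membership tests are independent — the yolk is not assumed to be a
subset of the white.  Ellipse constants live in the versioned constants
file; they are the published BOILED-Egg decision regions (digitized, as
the original model is only available graphically).

The model was calibrated on neutral drug-like molecules.  Zwitterionic
monomers (net charge 0 but charged atoms) are classified by the same
geometry and flagged with a warning, since they sit outside the model's
applicability domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .descriptors import CONSTANTS, compute_descriptors
from .molgraph import Molecule

__all__ = ["EggClassification", "boiled_egg", "screen_panel"]


@dataclass
class EggClassification:
    gi_absorption: str  # "high" | "low"
    bbb_permeant: str   # "yes" | "no"
    point: tuple[float, float]  # (tpsa, wlogp)
    warnings: tuple[str, ...] = ()


def _inside(ellipse: dict, tpsa: float, wlogp: float) -> bool:
    dx = (tpsa - ellipse["tpsa_center"]) / ellipse["tpsa_semiaxis"]
    dy = (wlogp - ellipse["wlogp_center"]) / ellipse["wlogp_semiaxis"]
    return dx * dx + dy * dy <= 1.0


def boiled_egg(tpsa: float, wlogp: float) -> EggClassification:
    """Classify a (TPSA, WLOGP) point: white => high GI, yolk => BBB."""
    egg = CONSTANTS["boiled_egg"]
    gi = "high" if _inside(egg["white"], tpsa, wlogp) else "low"
    bbb = "yes" if _inside(egg["yolk"], tpsa, wlogp) else "no"
    return EggClassification(gi_absorption=gi, bbb_permeant=bbb,
                             point=(tpsa, wlogp))


def classify_molecule(mol: Molecule) -> EggClassification:
    d = compute_descriptors(mol)
    cls = boiled_egg(d.tpsa, d.wlogp)
    warnings = []
    if mol.net_charge == 0 and any(a.formal_charge for a in mol.atoms):
        warnings.append("zwitterion: outside BOILED-Egg calibration domain")
    elif mol.net_charge != 0:
        warnings.append("net charge: outside BOILED-Egg calibration domain")
    cls.warnings = tuple(warnings)
    return cls


def screen_panel(panel: list[Molecule]) -> pd.DataFrame:
    """One BOILED-Egg classification row per molecule, input order kept."""
    rows = []
    for mol in panel:
        cls = classify_molecule(mol)
        rows.append({
            "identifier": mol.identifier,
            "tpsa": cls.point[0],
            "wlogp": cls.point[1],
            "gi_absorption": cls.gi_absorption,
            "bbb_permeant": cls.bbb_permeant,
            "warnings": ";".join(cls.warnings),
        })
    return pd.DataFrame(
        rows, columns=["identifier", "tpsa", "wlogp", "gi_absorption",
                       "bbb_permeant", "warnings"]).set_index("identifier")
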