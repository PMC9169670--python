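"""Packaged reference tables from the *Cryptoclidus eurymerus* study case.

These fixtures carry the printed measurement and result tables for the
mounted skeleton IGPB R 324: cord lengths of the humerus and femur
muscles at three flipper poses with their derived length-change columns,
the per-muscle forces obtained by superposition of the downstroke and
upstroke load cases, and the agonist/antagonist groupings.  They are
reference data for cross-checking and reporting — the pipeline never
needs them to run, and the force tables are for qualitative comparison
only (they depend on the original micro-CT geometry and on manual final
adjustments that are not reproducible).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "table1_fixture",
    "paper_force_fixture",
    "agonist_antagonist_fixture",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("flipperfea.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def table1_fixture() -> pd.DataFrame:
    """Cord lengths (cm) of 19 foreflipper and 22 hindflipper muscles at
    maximum ventral, neutral and maximum dorsal excursion, together with
    the printed derived percentage columns (kept exactly as printed,
    including internally inconsistent rows — see
    :func:`flipperfea.length_change.audit_table`)."""
    return _read("cord_lengths_table.csv")


def paper_force_fixture(bone: str = "both") -> pd.DataFrame:
    """Published per-muscle forces (N) by load-case superposition:
    19 humerus entries and 11 femur entries."""
    hum = _read("muscle_forces_humerus.csv")
    fem = _read("muscle_forces_femur.csv")
    if bone == "humerus":
        return hum
    if bone == "femur":
        return fem
    if bone == "both":
        return pd.concat([hum, fem], ignore_index=True)
    raise ValueError(f"bone must be humerus/femur/both, got {bone!r}")


def agonist_antagonist_fixture(bone: str) -> pd.DataFrame:
    """Agonist/antagonist muscle groupings for the humerus or femur."""
    if bone not in ("humerus", "femur"):
        raise ValueError(f"bone must be humerus or femur, got {bone!r}")
    return _read(f"agonist_antagonist_{bone}.csv")
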