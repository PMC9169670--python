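"""Functional superposition of load cases and stress-band reporting.

Bone adapts to the whole spectrum of loads it experiences, so the
long-term functional load is represented by combining the per-load-case
stress fields element by element: the envelope keeps the most tensile
first principal stress and the most compressive third principal stress
seen in any case (an algebraic per-element sum is available behind a
flag for comparison).  The compressive axis is then classified into the
low / moderate / high bands used for color-coded reporting, and the
maximum shear is summarized against the shear strength of bone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fe import StressField

__all__ = [
    "EnvelopeField",
    "BandClassification",
    "superpose",
    "classify_bands",
    "shear_summary",
    "BAND_EDGES",
    "SHEAR_STRENGTH_MPA",
]

# compressive stress bands (MPa) used in color-coded reporting:
# low (red/orange/yellow), moderate (green), high (turquoise/blue)
BAND_EDGES = (0.0, -3.6, -7.2, -10.8)
BAND_NAMES = ("low", "moderate", "high")
SHEAR_STRENGTH_MPA = 62.0  # lower end of the 62-72 MPa shear strength of bone


@dataclass
class EnvelopeField:
    """Per-element envelope over load cases."""

    sigma1_env: np.ndarray  # most tensile sigma1 across cases
    sigma3_env: np.ndarray  # most compressive sigma3 across cases
    case_label: np.ndarray  # index of the case contributing sigma3_env
    element_volumes: np.ndarray

    @property
    def tau_env(self) -> np.ndarray:
        return 0.5 * (self.sigma1_env - self.sigma3_env)


@dataclass
class BandClassification:
    band: np.ndarray  # per-element name in BAND_NAMES or "out_of_range"
    volume_fractions: dict  # band name -> fraction of total volume

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"band": list(self.volume_fractions), "volume_fraction": list(self.volume_fractions.values())}
        )


def superpose(fields: list, mode: str = "envelope") -> EnvelopeField:
    """Combine per-load-case stress fields element by element.

    ``envelope`` (default): per element, max of sigma1 and min of sigma3
    across cases — the functional superposition.  ``sum`` adds the fields
    algebraically (provided for comparison only).  A single field returns
    itself unchanged.
    """
    if not fields:
        raise ValueError("no stress fields to superpose")
    n = len(fields[0].sigma1)
    meshes = {id(f.mesh) for f in fields if f.mesh is not None}
    for f in fields:
        if len(f.sigma1) != n:
            raise ValueError("stress fields live on different meshes")
    if len(meshes) > 1:
        m0 = fields[0].mesh
        for f in fields[1:]:
            if f.mesh is not None and not np.array_equal(f.mesh.elements, m0.elements):
                raise ValueError("stress fields live on different meshes")
    vols = (
        np.abs(fields[0].mesh.volumes())
        if fields[0].mesh is not None
        else np.ones(n)
    )
    s1 = np.stack([f.sigma1 for f in fields])
    s3 = np.stack([f.sigma3 for f in fields])
    if mode == "envelope":
        label = np.argmin(s3, axis=0)
        return EnvelopeField(s1.max(axis=0), s3.min(axis=0), label, vols)
    if mode == "sum":
        return EnvelopeField(s1.sum(axis=0), s3.sum(axis=0), np.zeros(n, dtype=int), vols)
    raise ValueError(f"unknown superposition mode {mode!r}")


def classify_bands(env: EnvelopeField) -> BandClassification:
    """Classify each element's compressive envelope into the color bands.

    Bands are half-open on the most-compressive side: an element exactly
    on an edge (e.g. -3.6 MPa) belongs to the more compressive band.
    Elements more compressive than the last edge (or tensile, sigma3 > 0)
    are ``out_of_range``.  Volume fractions over all elements sum to 1.
    """
    s3 = env.sigma3_env
    band = np.full(len(s3), "out_of_range", dtype=object)
    for name, hi, lo in zip(BAND_NAMES, BAND_EDGES[:-1], BAND_EDGES[1:]):
        # interval (lo, hi]: lo is the more compressive edge
        sel = (s3 <= hi) & (s3 > lo)
        band[sel] = name
    total = env.element_volumes.sum()
    fractions = {}
    for name in BAND_NAMES + ("out_of_range",):
        fractions[name] = float(env.element_volumes[band == name].sum() / total)
    return BandClassification(band, fractions)


def shear_summary(tau: np.ndarray, volumes: np.ndarray | None = None) -> pd.DataFrame:
    """Mean and population SD of the max shear, unweighted and
    volume-weighted, with the safety ratio against bone shear strength.

    The element weighting behind the reported shear statistic is not
    uniquely defined for a model summary, so both variants are emitted.
    """
    tau = np.asarray(tau, dtype=float)
    rows = []
    mean_u = float(tau.mean())
    sd_u = float(tau.std())  # population (divide by N)
    rows.append(("unweighted", mean_u, sd_u))
    if volumes is not None:
        w = np.asarray(volumes, dtype=float)
        w = w / w.sum()
        mean_w = float((w * tau).sum())
        sd_w = float(np.sqrt((w * (tau - mean_w) ** 2).sum()))
        rows.append(("volume_weighted", mean_w, sd_w))
    return pd.DataFrame(
        [
            {
                "weighting": name,
                "mean_tau_mpa": m,
                "sd_tau_mpa": s,
                "safety_ratio_vs_62mpa": SHEAR_STRENGTH_MPA / m if m > 0 else np.inf,
            }
            for name, m, s in rows
        ]
    )
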