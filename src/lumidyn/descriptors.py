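"""Small deterministic dynamics descriptors.

Conversions and summaries used downstream of MD/tunnel analyses: the
crystallographic-style B-factor from a fluctuation profile, B = (8*pi^2/3) *
RMSF^2; per-enzyme z-standardization Z = (X - mu)/delta with the sample
(n-1) standard deviation; per-segment averaging; open/closed tunnel
classification against the water radius (1.4 A); and mean residue ellipticity
for CD spectra, Theta_MRE = Theta_obs * M_w * 100 / (n * c * l).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anm import SegmentSet

__all__ = [
    "bfactor_from_rmsf",
    "standardize_values",
    "segment_average",
    "classify_tunnel_frames",
    "mean_residue_ellipticity",
    "TunnelClassification",
    "WATER_RADIUS",
]

WATER_RADIUS = 1.4  # Angstrom

B_FACTOR_CONST = 8.0 * np.pi**2 / 3.0


def bfactor_from_rmsf(rmsf: np.ndarray) -> np.ndarray:
    """B-factor profile (A^2) from an RMSF profile (A): B = (8*pi^2/3)*RMSF^2."""
    r = np.asarray(rmsf, dtype=float)
    if np.any(r < 0):
        raise ValueError("RMSF values must be >= 0")
    return B_FACTOR_CONST * r**2


def standardize_values(values: np.ndarray) -> np.ndarray:
    """Z = (X - mu)/delta with the sample (n-1) standard deviation."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values to standardize")
    delta = np.std(x, ddof=1)
    if delta == 0:
        raise ValueError("constant profile: standard deviation is zero")
    return (x - np.mean(x)) / delta


def segment_average(profile: np.ndarray, segments: SegmentSet) -> dict[str, float]:
    """Arithmetic mean of the profile over each segment (1-based inclusive)."""
    x = np.asarray(profile, dtype=float)
    out = {}
    for seg in segments:
        if seg.end > len(x):
            raise ValueError(
                f"segment {seg.name} [{seg.start},{seg.end}] exceeds profile length {len(x)}"
            )
        out[seg.name] = float(np.mean(x[seg.indices()]))
    return out


@dataclass(frozen=True)
class TunnelClassification:
    labels: np.ndarray       # "open"/"closed" per frame
    threshold: float
    n_open: int
    n_closed: int
    open_mean: float | None
    open_sd: float | None
    closed_mean: float | None
    closed_sd: float | None


def classify_tunnel_frames(
    radii: np.ndarray, threshold: float = WATER_RADIUS
) -> TunnelClassification:
    """Label frames open (radius >= threshold) or closed (radius below it).

    A tunnel is closed when its bottleneck radius drops below the water
    radius; frames exactly at the threshold count as open.  Reports per-state
    count, mean and sample standard deviation.
    """
    r = np.asarray(radii, dtype=float)
    if r.size == 0:
        raise ValueError("empty bottleneck series")
    if np.any(r <= 0):
        raise ValueError("bottleneck radii must be > 0")
    closed = r < threshold
    labels = np.where(closed, "closed", "open")

    def stats(mask):
        vals = r[mask]
        if vals.size == 0:
            return None, None
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return float(np.mean(vals)), sd

    om, osd = stats(~closed)
    cm, csd = stats(closed)
    return TunnelClassification(
        labels=labels, threshold=threshold,
        n_open=int(np.sum(~closed)), n_closed=int(np.sum(closed)),
        open_mean=om, open_sd=osd, closed_mean=cm, closed_sd=csd,
    )


def mean_residue_ellipticity(
    theta_obs: float, M_w: float, n_residues: int, c_mg_ml: float, path_cm: float
) -> float:
    """Mean residue ellipticity (deg cm^2 dmol^-1) from observed ellipticity.

    Theta_MRE = Theta_obs * M_w * 100 / (n * c * l); the factor 100 converts
    the molecular weight to mg/dmol.  `c_mg_ml` in mg/ml, `path_cm` in cm.
    """
    if n_residues <= 0 or c_mg_ml <= 0 or path_cm <= 0:
        raise ValueError("n_residues, concentration and path length must be > 0")
    return theta_obs * M_w * 100.0 / (n_residues * c_mg_ml * path_cm)
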