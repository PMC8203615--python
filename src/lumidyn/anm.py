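"""Anisotropic network models and segment-centred motion cross-correlation.

An ANM places identical springs (constant gamma) between all Calpha pairs
within a distance cutoff.  The pseudo-inverse of the 3P x 3P Hessian over the
non-rigid modes gives per-residue squared fluctuations var(x) and the
residue-residue motion cross-correlation r(x, y).  Correlations are then
averaged over secondary-structure elements (SSEs) with fluctuation weighting:

    Ccor(SSE_i, SSE_j) =
        sum_{x in i} sum_{y in j} r(x,y) * sqrt(var(x) * var(y))
        / sqrt( [self-block sum of i] * [self-block sum of j] )

Appending every residue as its own one-residue segment extends the E x E
segment matrix to an (E + P) x (E + P) layout.  Subtracting the matrix of a
second structure (over a user-supplied mapping) yields a difference matrix M
with entries in [-2, 2]; a variant is annotated with 18 values of M: nine for
its mutated position against nine configured regions of interest and nine for
its host segment against the same regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CaStructure",
    "Segment",
    "SegmentSet",
    "ANMModel",
    "SegmentCcorMatrix",
    "DifferenceMatrix",
    "VariantAnnotation",
    "read_ca_structure",
    "build_anm",
    "segment_ccor",
    "difference_matrix",
    "annotate_variant",
    "DEFAULT_REGIONS",
]

DEFAULT_CUTOFF = 15.0  # Angstrom
DEFAULT_GAMMA = 1.0
RIGID_MODE_RTOL = 1e-6  # eigenvalues below this fraction of the largest are rigid


@dataclass
class CaStructure:
    """Ordered Calpha records of one chain.

    `residue_keys` preserves the source numbering (chain, resnum, insertion
    code); positional indices used by segments are 1-based over this order.
    """

    residue_keys: list[tuple[str, int, str]]
    coords: np.ndarray  # (P, 3), Angstrom
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (P, 3)")
        if len(self.residue_keys) != len(self.coords):
            raise ValueError("residue_keys and coords length mismatch")
        if len(self) < 3:
            raise ValueError("structure must have at least 3 residues")
        if len(set(self.residue_keys)) != len(self.residue_keys):
            raise ValueError("duplicate (chain, residue, insertion) keys")
        centered = self.coords - self.coords.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError("all residues are collinear")

    def __len__(self) -> int:
        return len(self.residue_keys)


def read_ca_structure(pdb_path: str, chain: str, label: str | None = None) -> CaStructure:
    """Read the Calpha trace of one chain from a PDB file (altloc 'A'/blank)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(pdb_path)
    atoms = pdb.get_structure(model=1, altloc="first", extra_fields=["occupancy"])
    chains = sorted(set(atoms.chain_id))
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not found; available chains: {chains}")
    mask = (atoms.chain_id == chain) & (atoms.atom_name == "CA") & ~atoms.hetero
    ca = atoms[mask]
    if ca.array_length() == 0:
        raise ValueError(f"no Calpha atoms in chain {chain!r} of {pdb_path}")
    keys = [
        (str(c), int(r), str(i))
        for c, r, i in zip(ca.chain_id, ca.res_id, ca.ins_code)
    ]
    return CaStructure(
        residue_keys=keys, coords=np.array(ca.coord, dtype=float),
        label=label or f"{pdb_path}:{chain}",
    )


@dataclass(frozen=True)
class Segment:
    """Inclusive 1-based positional range [start, end] over the residue order."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"segment {self.name}: need 1 <= start <= end")

    def indices(self) -> np.ndarray:
        return np.arange(self.start - 1, self.end)


@dataclass
class SegmentSet:
    segments: list[Segment]

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def names(self) -> list[str]:
        return [s.name for s in self.segments]

    def host_of(self, position: int) -> Segment:
        """Segment containing 1-based `position`; error names the neighbours."""
        for s in self.segments:
            if s.start <= position <= s.end:
                return s
        before = max((s for s in self.segments if s.end < position),
                     key=lambda s: s.end, default=None)
        after = min((s for s in self.segments if s.start > position),
                    key=lambda s: s.start, default=None)
        raise ValueError(
            f"position {position} lies outside every segment "
            f"(nearest: {before.name if before else '-'} / {after.name if after else '-'})"
        )

    @staticmethod
    def from_records(records: list[dict]) -> "SegmentSet":
        return SegmentSet([Segment(r["name"], int(r["start"]), int(r["end"]))
                           for r in records])


@dataclass
class ANMModel:
    hessian: np.ndarray        # (3P, 3P)
    eigenvalues: np.ndarray    # non-rigid, ascending
    eigenvectors: np.ndarray   # (3P, n_modes)
    var: np.ndarray            # (P,), per-residue squared fluctuation
    ccorr: np.ndarray          # (P, P), r(x, y)
    cutoff: float
    gamma: float

    @property
    def n_residues(self) -> int:
        return len(self.var)

    @property
    def covariance(self) -> np.ndarray:
        """Per-residue scalar covariance cov(x,y) = r * sqrt(var_x * var_y)."""
        s = np.sqrt(self.var)
        return self.ccorr * np.outer(s, s)


def build_anm(
    structure: CaStructure,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
) -> ANMModel:
    """Standard Calpha ANM: Hessian, fluctuations, cross-correlations.

    Raises if the contact network is disconnected at the chosen cutoff or if
    the number of near-zero (rigid-body) modes differs from six.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    xyz = structure.coords
    P = len(structure)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    contact = (dist < cutoff) & ~np.eye(P, dtype=bool)
    isolated = np.nonzero(~contact.any(axis=1))[0]
    if len(isolated):
        raise ValueError(
            f"residues with no neighbours within {cutoff} A: positions "
            f"{[int(i) + 1 for i in isolated]}"
        )

    H = np.zeros((3 * P, 3 * P))
    ii, jj = np.nonzero(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        d = diff[i, j]
        block = -gamma * np.outer(d, d) / (dist[i, j] ** 2)
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block

    evals, evecs = np.linalg.eigh(H)
    rigid = np.abs(evals) < RIGID_MODE_RTOL * evals[-1]
    n_rigid = int(np.sum(rigid))
    if n_rigid != 6:
        raise ValueError(
            f"expected 6 rigid-body modes, found {n_rigid}: the network may be "
            "disconnected or degenerate"
        )
    keep = ~rigid
    lam = evals[keep]
    V = evecs[:, keep]

    # covariance over non-rigid modes: C = V diag(1/lam) V^T, per-residue
    # 3x3 blocks reduced by trace
    Vw = V / np.sqrt(lam)
    Vr = Vw.reshape(P, 3, -1)
    cov = np.einsum("iam,jam->ij", Vr, Vr)
    var = np.diag(cov).copy()
    s = np.sqrt(var)
    ccorr = cov / np.outer(s, s)
    return ANMModel(
        hessian=H, eigenvalues=lam, eigenvectors=V,
        var=var, ccorr=ccorr, cutoff=cutoff, gamma=gamma,
    )


@dataclass
class SegmentCcorMatrix:
    labels: list[str]
    matrix: np.ndarray
    extended: bool = False
    n_segments: int = 0   # leading rows/cols that are true SSEs (rest residues)
    label_origin: str = ""

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def segment_ccor(
    model: ANMModel, segments: SegmentSet, extended: bool = False
) -> SegmentCcorMatrix:
    """Fluctuation-weighted segment-averaged cross-correlation matrix.

    With ``extended=True`` each residue is appended as its own one-residue
    segment, giving the (E + P) x (E + P) layout.  Entries whose self-block
    covariance sum is non-positive are undefined and reported as NaN with a
    warning (the normalization loses meaning there), never silently zeroed.
    """
    P = model.n_residues
    for s in segments:
        if s.end > P:
            raise ValueError(f"segment {s.name} [{s.start},{s.end}] exceeds {P} residues")
    blocks: list[tuple[str, np.ndarray]] = [
        (s.name, s.indices()) for s in segments
    ]
    if extended:
        blocks += [(f"res{i + 1}", np.array([i])) for i in range(P)]

    cov = model.covariance
    n = len(blocks)
    self_sums = np.array([cov[np.ix_(idx, idx)].sum() for _, idx in blocks])
    bad = self_sums <= 0
    if bad.any():
        warnings.warn(
            "segments with non-positive self-block covariance sum have undefined "
            f"Ccor and are reported as NaN: {[blocks[i][0] for i in np.nonzero(bad)[0]]}"
        )
    M = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            if bad[i] or bad[j]:
                M[i, j] = M[j, i] = np.nan
                continue
            num = cov[np.ix_(blocks[i][1], blocks[j][1])].sum()
            M[i, j] = M[j, i] = num / np.sqrt(self_sums[i] * self_sums[j])
    return SegmentCcorMatrix(
        labels=[b[0] for b in blocks], matrix=M, extended=extended,
        n_segments=len(segments),
    )


@dataclass
class DifferenceMatrix:
    """M = Ccor(A) - Ccor(B) over a shared label mapping; entries in [-2, 2]."""

    labels: list[str]          # labels of A retained by the mapping
    matrix: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def value(self, row: str, col: str) -> float:
        i = self.labels.index(row)
        j = self.labels.index(col)
        return float(self.matrix[i, j])


def difference_matrix(
    ccor_a: SegmentCcorMatrix,
    ccor_b: SegmentCcorMatrix,
    mapping: dict[str, str] | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> DifferenceMatrix:
    """Entrywise Ccor(A) - Ccor(B) over mapped labels.

    `mapping` pairs labels of A with labels of B (identity when omitted and
    the label sets agree).  Unmapped labels are dropped with a warning;
    duplicate mapping targets are rejected.
    """
    if mapping is None:
        common = [l for l in ccor_a.labels if l in set(ccor_b.labels)]
        mapping = {l: l for l in common}
    if not mapping:
        raise ValueError("empty mapping between the two matrices")
    targets = list(mapping.values())
    if len(set(targets)) != len(targets):
        raise ValueError("duplicate mapping targets")
    keys_a = [k for k in ccor_a.labels if k in mapping]
    dropped = [l for l in ccor_a.labels if l not in mapping]
    if dropped:
        warnings.warn(f"labels of {label_a} dropped by the mapping: {dropped[:10]}...")
    ia = [ccor_a.labels.index(k) for k in keys_a]
    try:
        ib = [ccor_b.labels.index(mapping[k]) for k in keys_a]
    except ValueError as exc:
        raise ValueError(f"mapping target missing from {label_b}: {exc}") from None
    A = ccor_a.matrix[np.ix_(ia, ia)]
    B = ccor_b.matrix[np.ix_(ib, ib)]
    M = A - B
    finite = M[np.isfinite(M)]
    if finite.size and (finite.min() < -2 - 1e-9 or finite.max() > 2 + 1e-9):
        raise AssertionError("difference-matrix entries escaped [-2, 2]")
    return DifferenceMatrix(labels=keys_a, matrix=M, label_a=label_a, label_b=label_b)


# Placeholder regions of interest: the study defined three groups of regions
# around the cap domain (mutated elements, catalytic loops, tunnel-lining
# elements); their identities live in supplementary tables, so this default
# config only fixes the *count* (nine) and must be overridden with real
# segment names for any real analysis.
DEFAULT_REGIONS = [f"region{i + 1}" for i in range(9)]


@dataclass(frozen=True)
class VariantAnnotation:
    variant_id: str
    position: int
    host_segment: str
    position_values: tuple[float, ...]   # 9 values: position vs each region
    segment_values: tuple[float, ...]    # 9 values: host segment vs each region
    regions: tuple[str, ...]

    @property
    def values(self) -> tuple[float, ...]:
        return self.position_values + self.segment_values


def annotate_variant(
    M: DifferenceMatrix,
    position: int,
    segments: SegmentSet,
    regions: list[str] | None = None,
    variant_id: str = "",
) -> VariantAnnotation:
    """Annotate a variant with 18 difference-matrix values.

    Nine values correlate the mutated position (as a one-residue segment row
    of the extended matrix, label ``res<position>``) with each configured
    region of interest, and nine correlate the position's host segment with
    the same regions.  Requires `M` built from extended matrices.
    """
    regions = list(DEFAULT_REGIONS if regions is None else regions)
    if len(regions) != 9:
        raise ValueError(f"exactly 9 regions of interest required, got {len(regions)}")
    pos_label = f"res{position}"
    if pos_label not in M.labels:
        raise ValueError(
            f"position {position} ({pos_label}) is not mapped in the difference matrix"
        )
    host = segments.host_of(position)
    if host.name not in M.labels:
        raise ValueError(f"host segment {host.name!r} is not mapped in the difference matrix")
    missing = [r for r in regions if r not in M.labels]
    if missing:
        raise ValueError(f"regions missing from the difference matrix: {missing}")
    pos_vals = tuple(M.value(pos_label, r) for r in regions)
    seg_vals = tuple(M.value(host.name, r) for r in regions)
    return VariantAnnotation(
        variant_id=variant_id or pos_label, position=position,
        host_segment=host.name, position_values=pos_vals,
        segment_values=seg_vals, regions=tuple(regions),
    )
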