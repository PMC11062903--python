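"""Molecular standardization, fingerprinting, similarity search and clustering.

Molecules are handled as 2-D structures throughout: a compound is standardized
to a canonical SMILES, hashed to a 2048-bit Morgan (circular, radius 2)
fingerprint, and compared to other compounds by Tanimoto similarity
``|A & B| / |A | B|``.  Similarity searching against a set of query (parent)
scaffolds, leader-style (Butina) clustering at a fixed similarity cutoff, and
the CNS MPO drug-likeness score complete the chemical-space toolbox used by
the discovery loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

FP_RADIUS = 2
FP_NBITS = 2048


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, mol_id: str | None = None):
        self.smiles = smiles
        self.mol_id = mol_id
        where = f" (id={mol_id!r})" if mol_id is not None else ""
        super().__init__(f"unparseable SMILES{where}: {smiles!r}")


@dataclass(frozen=True)
class MoleculeRecord:
    """A library member: identifier, raw/standardized SMILES and fingerprint."""

    id: str
    smiles_raw: str
    smiles_std: str
    fingerprint: np.ndarray  # uint8 vector, length FP_NBITS
    parent_id: str | None = None

    def __post_init__(self):
        if self.fingerprint.shape != (FP_NBITS,):
            raise ValueError(
                f"fingerprint must have length {FP_NBITS}, "
                f"got {self.fingerprint.shape}"
            )


@dataclass(frozen=True)
class SimilarityResult:
    query_id: str
    hit_id: str
    tanimoto: float


@dataclass(frozen=True)
class ClusterAssignment:
    molecule_id: str
    cluster_id: int
    is_centroid: bool


@dataclass(frozen=True)
class MpoProperties:
    """The six physicochemical inputs of the CNS MPO score.

    clogp/clogd are calculated octanol-water partition/distribution
    coefficients, molecular_weight in Da, tpsa in A^2, hbd_count the number of
    hydrogen-bond donors and pka_basic the pKa of the most basic centre.
    """

    clogp: float
    clogd: float
    molecular_weight: float
    tpsa: float
    hbd_count: float
    pka_basic: float

    def __post_init__(self):
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if self.hbd_count < 0:
            raise ValueError("hbd_count must be non-negative")


# ---------------------------------------------------------------------------
# standardization & fingerprints
# ---------------------------------------------------------------------------

_uncharger = rdMolStandardize.Uncharger()
_fragment_chooser = rdMolStandardize.LargestFragmentChooser()
_tautomer_enumerator = rdMolStandardize.TautomerEnumerator()


def standardize_smiles(smiles_raw: str, mol_id: str | None = None) -> str:
    """Return the canonical standardized SMILES for ``smiles_raw``.

    Pipeline: parse -> cleanup -> keep largest fragment -> neutralize charges
    -> canonical tautomer -> canonical SMILES.  The operation is idempotent:
    re-standardizing the output returns the same string.

    Raises
    ------
    SmilesParseError
        If the input does not parse; ``mol_id`` is included in the message.
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise SmilesParseError(smiles_raw, mol_id)
    mol = rdMolStandardize.Cleanup(mol)
    mol = _fragment_chooser.choose(mol)
    mol = _uncharger.uncharge(mol)
    mol = _tautomer_enumerator.Canonicalize(mol)
    return Chem.MolToSmiles(mol)


_morgan_generators: dict[tuple[int, int], object] = {}


def morgan_fingerprint(
    smiles_std: str, radius: int = FP_RADIUS, nbits: int = FP_NBITS
) -> np.ndarray:
    """Hashed circular fingerprint as a uint8 0/1 vector of length ``nbits``."""
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        raise SmilesParseError(smiles_std)
    key = (radius, nbits)
    gen = _morgan_generators.get(key)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
        _morgan_generators[key] = gen
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(nbits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return arr


def make_record(mol_id: str, smiles_raw: str, parent_id: str | None = None) -> MoleculeRecord:
    """Standardize and fingerprint one compound into a :class:`MoleculeRecord`."""
    smiles_std = standardize_smiles(smiles_raw, mol_id)
    return MoleculeRecord(
        id=mol_id,
        smiles_raw=smiles_raw,
        smiles_std=smiles_std,
        fingerprint=morgan_fingerprint(smiles_std),
        parent_id=parent_id,
    )


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity ``|a & b| / |a | b|`` of two binary vectors.

    1 means identical 2-D fingerprints; 0 means no shared set bits.  Both
    vectors all-zero is an undefined similarity and raises.
    """
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise ValueError("undefined similarity: both fingerprints are all-zero")
    return int(np.count_nonzero(a & b)) / union


def _stack_fps(records: Sequence[MoleculeRecord]) -> np.ndarray:
    return np.stack([r.fingerprint for r in records]).astype(bool)


def tanimoto_matrix(
    library: Sequence[MoleculeRecord], queries: Sequence[MoleculeRecord]
) -> np.ndarray:
    """Pairwise Tanimoto matrix, shape (len(library), len(queries))."""
    lib = _stack_fps(library)
    qry = _stack_fps(queries)
    inter = lib.astype(np.int32) @ qry.T.astype(np.int32)
    pop_l = lib.sum(axis=1, dtype=np.int32)[:, None]
    pop_q = qry.sum(axis=1, dtype=np.int32)[None, :]
    union = pop_l + pop_q - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    return sim


def similarity_search(
    library: Sequence[MoleculeRecord],
    queries: Sequence[MoleculeRecord],
    threshold: float,
) -> list[SimilarityResult]:
    """Library members whose *maximum* similarity over queries exceeds ``threshold``.

    The comparison is strict (``> threshold``), matching the discovery
    protocol's ">0.5 / >0.4 / >0.3" search tiers.  Each hit is annotated with
    the argmax query as its parent; ties on the maximum go to the first query
    in input order.
    """
    if not library or not queries:
        raise ValueError("library and query set must be non-empty")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    sim = tanimoto_matrix(library, queries)
    out: list[SimilarityResult] = []
    for i, rec in enumerate(library):
        row = sim[i]
        j = int(np.nanargmax(row))
        best = float(row[j])
        if best > threshold:
            out.append(
                SimilarityResult(query_id=queries[j].id, hit_id=rec.id, tanimoto=best)
            )
    return out


def annotate_parents(
    library: Sequence[MoleculeRecord],
    queries: Sequence[MoleculeRecord],
    threshold: float,
) -> list[MoleculeRecord]:
    """Return the similarity-search hits as records with ``parent_id`` filled in."""
    by_id = {r.id: r for r in library}
    return [
        replace(by_id[res.hit_id], parent_id=res.query_id)
        for res in similarity_search(library, queries, threshold)
    ]


# ---------------------------------------------------------------------------
# Butina (leader) clustering
# ---------------------------------------------------------------------------


def butina_cluster(
    library: Sequence[MoleculeRecord], cutoff: float = 0.75
) -> list[ClusterAssignment]:
    """Leader-style Tanimoto clustering at a similarity ``cutoff``.

    Neighbourhoods are all molecules with similarity >= cutoff (every molecule
    is its own neighbour).  Centroids are picked greedily by descending
    neighbour count, ties broken by ascending molecule id; remaining
    neighbours join the centroid's cluster and are removed from play.
    Molecules left without any unassigned neighbour become singletons.
    """
    if not library:
        raise ValueError("library must be non-empty")
    n = len(library)
    sim = tanimoto_matrix(library, library)
    neighbor = sim >= cutoff
    np.fill_diagonal(neighbor, True)

    unassigned = set(range(n))
    ids = [r.id for r in library]
    assignments: list[ClusterAssignment] = []
    cluster_id = 0
    while unassigned:
        # neighbour counts restricted to still-unassigned molecules
        best = min(
            unassigned,
            key=lambda i: (-int(neighbor[i, list(unassigned)].sum()), ids[i]),
        )
        members = sorted(j for j in unassigned if neighbor[best, j])
        for j in members:
            assignments.append(
                ClusterAssignment(
                    molecule_id=ids[j], cluster_id=cluster_id, is_centroid=(j == best)
                )
            )
            unassigned.discard(j)
        cluster_id += 1
    assignments.sort(key=lambda a: a.molecule_id)
    return assignments


# ---------------------------------------------------------------------------
# CNS MPO
# ---------------------------------------------------------------------------

# Piecewise-linear desirability transforms of the CNS multiparameter
# optimization (MPO) score: each maps a property to [0, 1]; the score is the
# sum of the six, in [0, 6].  Breakpoints follow the published desirability
# scheme (monotone ramps except TPSA, which is a hump).  See docs/methods.md.


def _ramp_down(x: float, lo: float, hi: float) -> float:
    """1 below ``lo``, 0 above ``hi``, linear in between."""
    if x <= lo:
        return 1.0
    if x >= hi:
        return 0.0
    return (hi - x) / (hi - lo)


def _tpsa_hump(x: float) -> float:
    """0 outside [20, 120], 1 on [40, 90], linear ramps in between."""
    if x <= 20 or x >= 120:
        return 0.0
    if 40 <= x <= 90:
        return 1.0
    if x < 40:
        return (x - 20) / 20.0
    return (120 - x) / 30.0


def cns_mpo_score(props: MpoProperties) -> float:
    """CNS MPO drug-likeness score in [0, 6]; >= 4 is considered favourable.

    Sum of six desirability transforms: clogP (1 -> 5 ramp), clogD (2 -> 4),
    molecular weight (360 -> 500 Da), TPSA (hump, optimum 40-90 A^2),
    hydrogen-bond donors (0.5 -> 3.5) and most-basic pKa (8 -> 10).  All six
    properties must be supplied; there is no neutral default.
    """
    for name in ("clogp", "clogd", "molecular_weight", "tpsa", "hbd_count", "pka_basic"):
        v = getattr(props, name)
        if v is None or not np.isfinite(v):
            raise ValueError(f"CNS MPO property {name!r} is missing or non-finite")
    return (
        _ramp_down(props.clogp, 1.0, 5.0)
        + _ramp_down(props.clogd, 2.0, 4.0)
        + _ramp_down(props.molecular_weight, 360.0, 500.0)
        + _tpsa_hump(props.tpsa)
        + _ramp_down(props.hbd_count, 0.5, 3.5)
        + _ramp_down(props.pka_basic, 8.0, 10.0)
    )


def mpo_properties_from_smiles(smiles: str, pka_basic: float) -> MpoProperties:
    """RDKit-computed MPO inputs for a molecule.

    clogD is approximated by clogP (no ionization model is bundled) and the
    basic pKa must be supplied by the caller -- it is not estimated.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    clogp = Descriptors.MolLogP(mol)
    return MpoProperties(
        clogp=clogp,
        clogd=clogp,
        molecular_weight=Descriptors.MolWt(mol),
        tpsa=Descriptors.TPSA(mol),
        hbd_count=Descriptors.NumHDonors(mol),
        pka_basic=pka_basic,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_compounds_csv(path) -> list[MoleculeRecord]:
    """Read an ``id,smiles[,parent_id,...]`` CSV into standardized records.

    Rows whose SMILES fail to parse raise :class:`SmilesParseError` naming the
    offending id.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    if "id" not in df.columns or "smiles" not in df.columns:
        raise ValueError(f"{path}: compounds CSV requires 'id' and 'smiles' columns")
    records = []
    for row in df.itertuples(index=False):
        parent = getattr(row, "parent_id", None)
        if parent is not None and (parent != parent or parent == ""):  # NaN/empty
            parent = None
        records.append(make_record(str(row.id), str(row.smiles), parent))
    return records


def write_compounds_csv(records: Iterable[MoleculeRecord], path) -> None:
    import pandas as pd

    records = list(records)
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles_std for r in records],
            "parent_id": [r.parent_id for r in records],
        }
    ).to_csv(path, index=False)
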