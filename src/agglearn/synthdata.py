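"""Synthetic libraries, potency landscapes and plate datasets.

The generators make the whole discovery loop runnable offline:

* ``generate_library`` enumerates a valence-valid combinatorial library from
  bundled scaffold and substituent fragments (seeded, deterministic).
* ``landscape_potency`` defines a hidden structure-activity landscape in
  which the normalized aggregation half-time is a noisy sigmoidal function of
  the maximum Tanimoto similarity to a set of hidden "parent" actives --
  mirroring the empirical observation that potency concentrates narrowly
  around parent scaffolds, which is also the operating assumption of a
  similarity-gated screening library.
* ``campaign_oracle`` wraps the landscape as a deterministic labelling
  function standing in for the wet aggregation assay.
* ``generate_trace_dataset`` writes plate-reader style ThT trace CSVs (plus
  plate map and ground-truth manifest) from per-compound logistic kinetics.

Default landscape conditions: amplitude 4 (a molecule identical to a parent
scaffold reaches a normalized half-time of ~5, matching the strongest assay
responses), midpoint similarity 0.55, width 0.08 and noise sd 0.2, which
place roughly 5-10% of the default library above the potency threshold of 2
-- the sparse-hit regime of an early-stage screen.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from agglearn.chemspace import MoleculeRecord, make_record, tanimoto_matrix
from agglearn.kinetics import AssayCondition, LogisticFit, logistic_mass_fraction

__all__ = [
    "LandscapeSpec",
    "SyntheticLibrary",
    "SCAFFOLDS",
    "SUBSTITUENTS",
    "DEFAULT_HIDDEN_ACTIVES",
    "generate_library",
    "landscape_potency",
    "campaign_oracle",
    "generate_trace_dataset",
]

# Bundled fragment space: two-slot aromatic scaffolds (diaryl cores spanning
# the pyrazolidinedione-like chemotypes of the assay's parent compounds plus
# unrelated decoy chemotypes) crossed with common aryl substituents.
SCAFFOLDS: tuple[str, ...] = (
    "O=C1CC(=O)N(c2ccc({r1})cc2)N1c1ccc({r2})cc1",  # 1,2-diaryl pyrazolidine-3,5-dione
    "O=C1CC(=O)N(c2ccc({r1})cc2)N1C{r2}",            # N-alkyl pyrazolidinedione
    "c1cc({r1})ccc1-c1nc2cc({r2})ccc2[nH]1",         # 2-aryl benzimidazole
    "O=C(Nc1ccc({r1})cc1)c1ccc({r2})o1",             # furan-2-carboxanilide
    "O=C(Nc1ccc({r1})cc1)c1ccc({r2})s1",             # thiophene-2-carboxanilide
    "c1cc({r1})ccc1-c1ccc({r2})cc1",                 # biphenyl
    "O=C(/C=C/c1ccc({r1})cc1)c1ccc({r2})cc1",        # chalcone
    "c1cc({r1})ccc1-n1cc(cn1)-c1ccc({r2})cc1",       # 1,4-diaryl pyrazole
    "O=C(Nc1ccc({r1})cc1)Nc1ccc({r2})cc1",           # diaryl urea
    "c1cc({r1})ccc1Oc1ccc({r2})cc1",                 # diaryl ether
    "O=S(=O)(Nc1ccc({r1})cc1)c1ccc({r2})cc1",        # diaryl sulfonamide
    "c1cc({r1})ccc1-c1nnc(o1)-c1ccc({r2})cc1",       # 1,3,4-oxadiazole
)

SUBSTITUENTS: tuple[str, ...] = (
    "C", "O", "OC", "N", "F", "Cl", "Br", "C#N", "C(F)(F)F",
    "C(=O)O", "C(=O)N", "[N+](=O)[O-]", "CC", "OCC", "S(=O)(=O)N",
)

# Hidden parent actives of the default landscape: a single chemotype (the
# diaryl pyrazolidinedione scaffold) with two specific decorations, keeping
# the potent region a narrow island (~5-10% of the default library) amid
# eleven decoy chemotypes -- the sparse-hit regime of an early-stage screen.
DEFAULT_HIDDEN_ACTIVES: tuple[str, ...] = (
    SCAFFOLDS[0].format(r1="O", r2="Cl"),
    SCAFFOLDS[0].format(r1="C(=O)N", r2="F"),
)


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of the hidden structure-activity landscape."""

    hidden_actives: tuple[str, ...] = DEFAULT_HIDDEN_ACTIVES
    amplitude: float = 4.0
    midpoint: float = 0.55
    width: float = 0.08
    noise_sd: float = 0.2
    seed: int = 0
    floor: float = 0.1

    def __post_init__(self):
        if self.amplitude <= 0 or self.width <= 0:
            raise ValueError("amplitude and width must be positive")
        if not (0 < self.midpoint < 1):
            raise ValueError("midpoint must be in (0, 1)")


@dataclass(frozen=True)
class SyntheticLibrary:
    molecules: tuple[MoleculeRecord, ...]
    true_potency: np.ndarray | None = None  # hidden from learners

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.molecules]


def generate_library(
    n: int,
    seed: int = 0,
    scaffolds: Sequence[str] = SCAFFOLDS,
    substituents: Sequence[str] = SUBSTITUENTS,
) -> SyntheticLibrary:
    """Seeded sample of ``n`` molecules from the combinatorial fragment space.

    The full scaffold x substituent x substituent enumeration is shuffled
    with ``seed`` and molecules are standardized and collected in order,
    skipping any whose canonical SMILES has already been taken (symmetric
    scaffolds collapse r1/r2 swaps), until ``n`` unique molecules are found.
    Identical seeds give identical libraries.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    combos = [
        s.format(r1=r1, r2=r2)
        for s in scaffolds
        for r1 in substituents
        for r2 in substituents
    ]
    if n > len(combos):
        raise ValueError(f"n={n} exceeds enumerable space ({len(combos)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    width = len(str(len(combos)))
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for idx in order:
        rec = make_record(f"SYN-{len(records):0{width}d}", combos[idx])
        if rec.smiles_std in seen:
            continue
        seen.add(rec.smiles_std)
        records.append(rec)
        if len(records) == n:
            break
    if len(records) < n:
        raise ValueError(
            f"n={n} exceeds the number of unique standardized molecules "
            f"({len(records)})"
        )
    return SyntheticLibrary(molecules=tuple(records))


def _stable_molecule_seed(seed: int, mol_id: str) -> int:
    digest = hashlib.sha256(f"{seed}:{mol_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _max_similarity_to_actives(
    library: Sequence[MoleculeRecord], spec: LandscapeSpec
) -> np.ndarray:
    actives = [make_record(f"ACT-{i}", smi) for i, smi in enumerate(spec.hidden_actives)]
    sim = tanimoto_matrix(list(library), actives)
    return np.nanmax(sim, axis=1)


def landscape_potency(
    library: SyntheticLibrary, spec: LandscapeSpec = LandscapeSpec()
) -> SyntheticLibrary:
    """Attach hidden true potencies (normalized half-times) to a library.

    potency = 1 + amplitude * logistic((s - midpoint)/width) + noise, where s
    is the molecule's maximum Tanimoto similarity to the hidden actives;
    noise is Gaussian, seeded per molecule id, and values are floored.
    """
    s = _max_similarity_to_actives(library.molecules, spec)
    base = 1.0 + spec.amplitude / (1.0 + np.exp(-(s - spec.midpoint) / spec.width))
    if spec.noise_sd > 0:
        noise = np.array(
            [
                np.random.default_rng(_stable_molecule_seed(spec.seed, m.id)).normal(
                    0.0, spec.noise_sd
                )
                for m in library.molecules
            ]
        )
    else:
        noise = 0.0
    potency = np.maximum(base + noise, spec.floor)
    return SyntheticLibrary(molecules=library.molecules, true_potency=potency)


def campaign_oracle(
    library: SyntheticLibrary, spec: LandscapeSpec = LandscapeSpec()
) -> Callable[[str], float]:
    """Deterministic labelling function id -> normalized half-time.

    Stands in for the aggregation assay: repeated queries return identical
    values, consistent with :func:`landscape_potency` on the same spec.
    """
    labelled = (
        library
        if library.true_potency is not None
        else landscape_potency(library, spec)
    )
    table = dict(zip(labelled.ids, np.asarray(labelled.true_potency, dtype=float)))

    def oracle(mol_id: str) -> float:
        if mol_id not in table:
            raise KeyError(f"unknown molecule id {mol_id!r}")
        return table[mol_id]

    return oracle


# ---------------------------------------------------------------------------
# plate datasets
# ---------------------------------------------------------------------------


def generate_trace_dataset(
    compound_fits: dict[str, LogisticFit],
    out_dir: Path | str,
    condition: AssayCondition = AssayCondition(),
    duration_h: float = 125.0,
    n_points: int = 120,
    n_replicates: int = 3,
    noise_sd: float = 0.02,
    seed: int = 0,
    gain: float = 1000.0,
    offset: float = 50.0,
    plate: str = "P1",
) -> tuple[Path, Path, Path]:
    """Write a plate-shaped ThT dataset for the given per-compound kinetics.

    ``compound_fits`` maps compound id (must include ``"DMSO"``, the control)
    to its generalized-logistic parameters.  Signals are mass fractions
    scaled by ``gain`` and shifted by ``offset`` (exercising normalization)
    with i.i.d. Gaussian noise.  Returns paths of the traces CSV, plate-map
    CSV and ground-truth manifest CSV; byte-identical for a fixed seed.
    """
    if "DMSO" not in compound_fits:
        raise ValueError('compound_fits must include the "DMSO" control')
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, duration_h, n_points)

    trace_rows = []
    map_rows = []
    manifest_rows = []
    wells = iter(f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13))
    for comp_id, fit in compound_fits.items():
        for rep in range(n_replicates):
            well = next(wells)
            mf = logistic_mass_fraction(times, fit.kappa, fit.a, fit.c)
            sig = offset + gain * (mf + rng.normal(0.0, noise_sd, size=mf.shape))
            trace_rows.extend(
                {
                    "plate": plate,
                    "well": well,
                    "time_h": f"{t:.6f}",
                    "fluorescence": f"{s:.6f}",
                }
                for t, s in zip(times, sig)
            )
            map_rows.append(
                {
                    "plate": plate,
                    "well": well,
                    "compound_id": comp_id,
                    "compound_conc_uM": condition.compound_conc if comp_id != "DMSO" else 0.0,
                    "monomer_conc_uM": condition.m_tot,
                    "seed_conc_nM": condition.seed_conc * 1000.0,
                    "replicate": rep,
                    "role": "control" if comp_id == "DMSO" else "compound",
                }
            )
        manifest_rows.append(
            {
                "compound_id": comp_id,
                "kappa": fit.kappa,
                "a": fit.a,
                "t_half": fit.t_half,
                "k2_rel": (fit.kappa / compound_fits["DMSO"].kappa) ** 2,
            }
        )

    traces_path = out_dir / "traces.csv"
    platemap_path = out_dir / "platemap.csv"
    manifest_path = out_dir / "manifest.csv"
    pd.DataFrame(trace_rows).to_csv(traces_path, index=False)
    pd.DataFrame(map_rows).to_csv(platemap_path, index=False)
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    return traces_path, platemap_path, manifest_path


def read_trace_dataset(
    traces_path, platemap_path, condition_defaults: AssayCondition = AssayCondition()
):
    """Load a traces CSV + plate map into AggregationTrace objects (raw)."""
    from agglearn.kinetics import AggregationTrace

    traces = pd.read_csv(traces_path)
    platemap = pd.read_csv(platemap_path)
    out = []
    for row in platemap.itertuples(index=False):
        sel = traces[(traces["plate"] == row.plate) & (traces["well"] == row.well)]
        cond = AssayCondition(
            m_tot=float(row.monomer_conc_uM),
            seed_conc=float(row.seed_conc_nM) / 1000.0,
            compound_id=str(row.compound_id),
            compound_conc=float(row.compound_conc_uM),
            temperature=condition_defaults.temperature,
            ph=condition_defaults.ph,
        )
        out.append(
            AggregationTrace(
                time=sel["time_h"].to_numpy(dtype=float),
                signal=sel["fluorescence"].to_numpy(dtype=float),
                condition=cond,
                replicate=int(row.replicate),
            )
        )
    return out
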