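"""Deterministic synthetic-data generators with planted structure.

Every input the pipeline consumes can be generated here: expression
datasets whose high/low classes are drawn from residue distributions with a
known frequency ratio (so AEI recovery is testable against closed-form
ground truth), homolog families with planted conserved positions, and
pretraining corpora with optional embedded motifs so MLM learning is
detectable above chance.  Generators are pure functions of their spec and
seed, and can also emit PaxDB-dialect TSV + FASTA files so the file readers
are exercised by the same fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .composition_stats import AEITable
from .dataset_builder import ExpressionDataset, LabeledSequence
from .io_formats import STANDARD_AA, write_fasta

#: Residues consistently enriched in highly expressed proteins across
#: species (AEI > 1): K, A, G, D, E, V.
FAVORABLE_RESIDUES: tuple[str, ...] = tuple("KAGDEV")


def _uniform_dist() -> dict[str, float]:
    return {aa: 1 / 20 for aa in STANDARD_AA}


def biased_distribution(
    favored: Sequence[str] = FAVORABLE_RESIDUES, factor: float = 2.0
) -> dict[str, float]:
    """Uniform background with ``favored`` residues up-weighted by ``factor``."""
    w = {aa: (factor if aa in favored else 1.0) for aa in STANDARD_AA}
    total = sum(w.values())
    return {aa: v / total for aa, v in w.items()}


@dataclass(frozen=True)
class PlantedExpressionSpec:
    """Generative recipe for a labeled expression dataset.

    High and low classes draw residues i.i.d. from their own distributions;
    the implied ground-truth AEI is ``high_dist[a] / low_dist[a]``.
    Log-abundance follows ``alpha * favorable-fraction + N(0, sigma)``, with
    draws re-ordered inside each class so tertile ranking reproduces the
    planted labels exactly.
    """

    n_per_class: int = 1000
    length_range: tuple[int, int] = (50, 200)
    high_dist: Mapping[str, float] = field(default_factory=lambda: biased_distribution())
    low_dist: Mapping[str, float] = field(default_factory=_uniform_dist)
    alpha: float = 4.0
    sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name, dist in (("high_dist", self.high_dist), ("low_dist", self.low_dist)):
            if abs(sum(dist.values()) - 1) > 1e-9:
                raise ValueError(f"{name} must sum to 1")

    def ground_truth_aei(self, species_id: str = "synthetic") -> AEITable:
        for aa in STANDARD_AA:
            if (self.low_dist[aa] == 0) != (self.high_dist[aa] == 0):
                raise ValueError(f"degenerate distribution at residue {aa}")
        return AEITable(
            species_id=species_id,
            aei={aa: self.high_dist[aa] / self.low_dist[aa] for aa in STANDARD_AA},
        )


def _draw_sequence(rng: np.random.Generator, dist: Mapping[str, float],
                   length_range: tuple[int, int]) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    alphabet = list(dist)
    probs = np.array([dist[a] for a in alphabet])
    return "".join(rng.choice(alphabet, size=length, p=probs))


def gen_expression_dataset(
    spec: PlantedExpressionSpec, species_id: str = "synthetic"
) -> tuple[ExpressionDataset, AEITable]:
    """Generate a labeled dataset plus its ground-truth AEI table.

    Abundances correlate with favorable-residue content within each class,
    but are rank-shifted so every high-class abundance exceeds every
    low-class abundance — tertile labeling then reproduces the planted
    classes exactly, decoupling AEI recovery tests from labeling noise.
    """
    truth = spec.ground_truth_aei(species_id)
    rng = np.random.default_rng(spec.seed)
    entries: list[LabeledSequence] = []
    raw: dict[str, list[tuple[str, float]]] = {}
    for cls, dist in (("high", spec.high_dist), ("low", spec.low_dist)):
        rows = []
        for i in range(spec.n_per_class):
            seq = _draw_sequence(rng, dist, spec.length_range)
            fav = sum(seq.count(a) for a in FAVORABLE_RESIDUES) / len(seq)
            log_ab = spec.alpha * fav + rng.normal(0, spec.sigma)
            rows.append((seq, log_ab))
        raw[cls] = rows
    # shift low-class log-abundances below the high-class minimum
    high_vals = [v for _, v in raw["high"]]
    low_vals = [v for _, v in raw["low"]]
    offset = (max(low_vals) - min(high_vals)) + 1.0
    counter = 0
    for cls, rows in raw.items():
        for seq, log_ab in rows:
            if cls == "low":
                log_ab -= offset
            counter += 1
            entries.append(
                LabeledSequence(
                    protein_id=f"{species_id}_{cls}_{counter:05d}",
                    sequence=seq,
                    abundance=float(math.exp(log_ab)),
                    expr_class=cls,
                )
            )
    dataset = ExpressionDataset(
        species_id=species_id,
        entries=entries,
        provenance={"generator": "planted-expression", "seed": spec.seed,
                    "n_per_class": spec.n_per_class},
    )
    return dataset, truth


def write_expression_fixture(
    dataset: ExpressionDataset, out_dir: str | Path
) -> tuple[Path, Path]:
    """Emit the dataset as a PaxDB-dialect abundance TSV + FASTA pair."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / f"{dataset.species_id}.abundance.tsv"
    fasta = out_dir / f"{dataset.species_id}.fasta"
    with open(tsv, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# synthetic abundance table for {dataset.species_id}\n")
        fh.write("# protein_id\tabundance_ppm\n")
        for e in dataset.entries:
            fh.write(f"{e.protein_id}\t{e.abundance!r}\n")
    write_fasta({e.protein_id: e.sequence for e in dataset.entries}, fasta)
    return tsv, fasta


@dataclass(frozen=True)
class PlantedFamilySpec:
    """Homolog family with per-position substitution tolerance.

    ``tolerance[i] = 0`` plants a conserved column; otherwise position i is
    substituted with that probability, drawing uniformly from the allowed
    alphabet (default: the 19 non-wild-type residues).
    """

    seed_sequence: str
    n_members: int = 100
    tolerance: tuple[float, ...] = ()
    allowed: Mapping[int, Sequence[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        tol = self.tolerance or tuple(0.0 for _ in self.seed_sequence)
        if len(tol) != len(self.seed_sequence):
            raise ValueError("tolerance length must match seed sequence length")
        if any(not 0 <= t <= 1 for t in tol):
            raise ValueError("tolerances must lie in [0, 1]")
        object.__setattr__(self, "tolerance", tuple(tol))


def gen_homolog_family(spec: PlantedFamilySpec) -> list[str]:
    """Generate family members by independent per-position substitution."""
    rng = np.random.default_rng(spec.seed)
    members = []
    for _ in range(spec.n_members):
        chars = []
        for i, (wt, tol) in enumerate(zip(spec.seed_sequence, spec.tolerance)):
            if tol > 0 and rng.random() < tol:
                pool = list(spec.allowed.get(i, [aa for aa in STANDARD_AA if aa != wt]))
                chars.append(str(rng.choice(pool)))
            else:
                chars.append(wt)
        members.append("".join(chars))
    return members


def gen_corpus(
    n: int,
    length_range: tuple[int, int] = (30, 100),
    seed: int = 0,
    background: Mapping[str, float] | None = None,
    motif: str | None = None,
    motif_rate: float = 0.0,
) -> list[str]:
    """Random sequence corpus for MLM pretraining fixtures.

    Optionally embeds ``motif`` at a random position in a ``motif_rate``
    fraction of sequences, giving the masked-token objective learnable
    structure beyond background composition.
    """
    if n < 1:
        raise ValueError("corpus size must be >= 1")
    rng = np.random.default_rng(seed)
    dist = dict(background) if background else _uniform_dist()
    corpus = []
    for _ in range(n):
        seq = _draw_sequence(rng, dist, length_range)
        if motif and rng.random() < motif_rate:
            pos = int(rng.integers(0, len(seq) - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        corpus.append(seq)
    return corpus
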