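"""Build class-pure, redundancy-reduced expression datasets.

Pipeline: rank proteins by abundance and split into tertiles (high /
medium / low), greedily cluster sequences at 90% identity (CD-HIT style),
keep a cluster's representative only when every member carries the same
high or low label, then require > 1000 surviving entries for "core" status.

Tertile rule: records are sorted by abundance descending (ties broken by
protein id ascending) and the first ceil(N/3) are high; the remainder is
split as evenly as possible favouring medium over low.  Identity between
two sequences is the number of matched positions in a global alignment
divided by the length of the shorter sequence, mirroring CD-HIT's default
normalisation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from Bio import Align
from sklearn.model_selection import StratifiedKFold, train_test_split

from .io_formats import AbundanceRecord, read_abundance_table, read_fasta

logger = logging.getLogger(__name__)

ExprClass = Literal["high", "medium", "low"]


@dataclass(frozen=True)
class LabeledSequence:
    protein_id: str
    sequence: str
    abundance: float
    expr_class: ExprClass

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: empty sequence")


@dataclass
class ExpressionDataset:
    """High/low labeled, redundancy-reduced sequences for one species."""

    species_id: str
    entries: list[LabeledSequence]
    provenance: dict = field(default_factory=dict)

    @property
    def is_core(self) -> bool:
        """True when the dataset is large enough for model training (> 1000)."""
        return len(self.entries) > 1000

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.expr_class == "medium":
                raise ValueError("ExpressionDataset entries must be high or low")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("protein_id\texpr_class\tabundance\tsequence\n")
            for e in self.entries:
                fh.write(f"{e.protein_id}\t{e.expr_class}\t{e.abundance!r}\t{e.sequence}\n")
        sidecar = Path(path).with_suffix(Path(path).suffix + ".provenance.json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, default=str) + "\n")


@dataclass(frozen=True)
class SplitSpec:
    """Independent test split plus stratified cross-validation folds."""

    test_fraction: float = 0.2
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class Cluster:
    representative: str  # sequence id
    members: list[str]


def tertile_sizes(n: int) -> tuple[int, int, int]:
    """Sizes of (high, medium, low) tertiles; remainder goes high then medium."""
    n_high = math.ceil(n / 3)
    rest = n - n_high
    n_medium = math.ceil(rest / 2)
    return n_high, n_medium, rest - n_medium


def assign_abundance_classes(
    records: Sequence[AbundanceRecord],
) -> dict[str, ExprClass]:
    """Rank by abundance and assign high/medium/low tertile labels.

    Sorted by abundance descending, ties broken by protein id ascending, so
    at an exact boundary tie the lexicographically smaller id takes the
    higher class.
    """
    if len(records) < 3:
        raise ValueError("tertile labeling requires at least 3 records")
    ranked = sorted(records, key=lambda r: (-r.abundance, r.protein_id))
    n_high, n_medium, n_low = tertile_sizes(len(ranked))
    labels: dict[str, ExprClass] = {}
    for i, rec in enumerate(ranked):
        if i < n_high:
            labels[rec.protein_id] = "high"
        elif i < n_high + n_medium:
            labels[rec.protein_id] = "medium"
        else:
            labels[rec.protein_id] = "low"
    return labels


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity normalised by the shorter sequence length."""
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def cluster_identity_greedy(
    sequences: Mapping[str, str], threshold: float = 0.90
) -> list[Cluster]:
    """Greedy incremental identity clustering in the CD-HIT style.

    Sequences are sorted by length descending (ties by id for determinism);
    each joins the first existing cluster whose *representative* it matches
    at >= threshold identity, else founds a new cluster.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not 0 < threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    aligner = _make_aligner()
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    clusters: list[Cluster] = []
    for sid in order:
        seq = sequences[sid]
        for cl in clusters:
            if pairwise_identity(sequences[cl.representative], seq, aligner) >= threshold:
                cl.members.append(sid)
                break
        else:
            clusters.append(Cluster(representative=sid, members=[sid]))
    return clusters


def select_class_pure_representatives(
    clusters: Sequence[Cluster],
    labels: Mapping[str, ExprClass],
    sequences: Mapping[str, str],
    abundances: Mapping[str, float],
    species_id: str,
) -> ExpressionDataset:
    """Keep representatives of clusters whose members all share one high/low label.

    Clusters containing any medium member, or mixing high and low, are
    discarded entirely — the conservative reading that prevents near-duplicate
    leakage between classes.
    """
    entries: list[LabeledSequence] = []
    n_discarded = 0
    for cl in clusters:
        member_classes = {labels[m] for m in cl.members}
        if len(member_classes) == 1 and member_classes <= {"high", "low"}:
            rep = cl.representative
            entries.append(
                LabeledSequence(
                    protein_id=rep,
                    sequence=sequences[rep],
                    abundance=abundances[rep],
                    expr_class=next(iter(member_classes)),
                )
            )
        else:
            n_discarded += 1
    n_high = sum(1 for e in entries if e.expr_class == "high")
    n_low = len(entries) - n_high
    logger.info(
        "%s: kept %d class-pure representatives (%d high / %d low), discarded %d clusters",
        species_id, len(entries), n_high, n_low, n_discarded,
    )
    return ExpressionDataset(species_id=species_id, entries=entries)


def build_species_dataset(
    abundance_path: str | Path,
    fasta_path: str | Path,
    species_id: str,
    identity_threshold: float = 0.90,
) -> tuple[ExpressionDataset, dict]:
    """End-to-end dataset construction: read, label, cluster, purify, flag.

    Returns the dataset and a stage-count report.  Datasets with <= 1000
    surviving entries are returned but flagged non-core.
    """
    records = read_abundance_table(abundance_path, species_id)
    sequences = read_fasta(fasta_path)
    joined = [r for r in records if r.protein_id in sequences]
    n_dropped = len(records) - len(joined)
    if n_dropped:
        logger.info("%s: %d abundance ids had no sequence and were dropped", species_id, n_dropped)
    if len(joined) < 3:
        raise ValueError(f"{species_id}: fewer than 3 joinable records")
    labels = assign_abundance_classes(joined)
    seq_map = {r.protein_id: sequences[r.protein_id] for r in joined}
    abund_map = {r.protein_id: r.abundance for r in joined}
    clusters = cluster_identity_greedy(seq_map, threshold=identity_threshold)
    dataset = select_class_pure_representatives(
        clusters, labels, seq_map, abund_map, species_id
    )
    report = {
        "n_abundance_records": len(records),
        "n_joined": len(joined),
        "n_clusters": len(clusters),
        "n_retained": len(dataset.entries),
        "n_high": sum(1 for e in dataset.entries if e.expr_class == "high"),
        "n_low": sum(1 for e in dataset.entries if e.expr_class == "low"),
        "is_core": dataset.is_core,
        "identity_threshold": identity_threshold,
    }
    dataset.provenance = report
    if not dataset.is_core:
        logger.warning("%s: only %d entries — flagged non-core", species_id, len(dataset.entries))
    return dataset, report


@dataclass(frozen=True)
class DatasetSplits:
    """Index-based test split and cross-validation folds over a dataset."""

    test_idx: tuple[int, ...]
    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]  # (train, val) per fold


def make_splits(dataset: ExpressionDataset, spec: SplitSpec) -> DatasetSplits:
    """Stratified test split plus stratified k-fold partition of the rest.

    Deterministic under ``spec.seed``; folds are disjoint and cover the
    non-test entries; class proportions are preserved within one entry.
    """
    y = np.array([1 if e.expr_class == "high" else 0 for e in dataset.entries])
    for cls in (0, 1):
        if (y == cls).sum() < spec.n_folds + 1:
            raise ValueError(
                f"class {cls} has fewer than n_folds+1 = {spec.n_folds + 1} entries"
            )
    idx = np.arange(len(y))
    trainval_idx, test_idx = train_test_split(
        idx, test_size=spec.test_fraction, random_state=spec.seed, stratify=y
    )
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    folds = []
    for tr, va in skf.split(trainval_idx, y[trainval_idx]):
        folds.append((tuple(int(i) for i in trainval_idx[tr]),
                      tuple(int(i) for i in trainval_idx[va])))
    return DatasetSplits(
        test_idx=tuple(int(i) for i in sorted(test_idx)), folds=tuple(folds)
    )


def parse_cdhit_clstr(path: str | Path) -> list[Cluster]:
    """Parse a CD-HIT ``.clstr`` file for parity checks against the greedy clusterer."""
    clusters: list[Cluster] = []
    current: list[str] = []
    rep: str | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith(">Cluster"):
                if current:
                    clusters.append(Cluster(representative=rep, members=current))
                current, rep = [], None
            elif line.strip():
                sid = line.split(">", 1)[1].split("...", 1)[0]
                current.append(sid)
                if line.rstrip().endswith("*"):
                    rep = sid
    if current:
        clusters.append(Cluster(representative=rep, members=current))
    return clusters
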