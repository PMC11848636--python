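"""Sequence-composition statistics linking amino-acid usage to expression.

The central quantities:

* **AEI** (amino-acid expression index): per species, the ratio of an amino
  acid's expected frequency among high-expression proteins to its expected
  frequency among low-expression proteins.  ``AEI_a > 1`` marks residues
  enriched in highly expressed proteins.
* **SRAB** (strength of relative amino-acid bias): per protein, a
  geometric-mean-style aggregate of AEI values over the sequence,

  .. math:: \\mathrm{SRAB} = \\exp\\Bigl(\\frac{1}{n-1}\\sum_{i=1}^{n}
            \\log\\bigl(1 + \\mathrm{AEI}(a_i)\\bigr)\\Bigr)

  mirroring the relative codon bias strength (RCBS) construction at the
  amino-acid level.  Higher SRAB predicts higher soluble expression in the
  host whose AEI table is used.

The module also covers the two supporting analyses: mean biosynthetic cost
per protein versus abundance, and AAindex physicochemical property
correlation with expression (z-scored property matrix, per-species Spearman
correlations, hierarchical clustering of the property matrix).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_formats import STANDARD_AA, PropertyIndex, CostTable
from .dataset_builder import ExpressionDataset

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass(frozen=True)
class ClassFrequencyProfile:
    """Mean amino-acid frequency vectors of the high and low classes.

    Each vector is the arithmetic mean of per-sequence frequency vectors
    (not pooled residue counts), so every protein contributes equally
    regardless of length.
    """

    a_h: np.ndarray
    a_l: np.ndarray
    n_high: int
    n_low: int


@dataclass(frozen=True)
class AEITable:
    """Per-species amino-acid expression index for the 20 standard residues."""

    species_id: str
    aei: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.aei) != set(STANDARD_AA):
            raise ValueError("AEI table must cover exactly the 20 standard residues")
        for aa, v in self.aei.items():
            if not v > 0:
                raise ValueError(f"AEI for {aa} must be > 0, got {v}")

    def __getitem__(self, aa: str) -> float:
        return self.aei[aa]


@dataclass(frozen=True)
class SrabResult:
    """SRAB score of one protein under one AEI table."""

    value: float
    n_residues: int
    per_residue_aei: tuple[float, ...]


@dataclass(frozen=True)
class StandardizedPropertyMatrix:
    """Row-standardized AAindex property matrix (properties x 20 residues)."""

    accessions: tuple[str, ...]
    raw: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    z: np.ndarray


@dataclass(frozen=True)
class PropertyCorrelationResult:
    """Per-property Spearman correlation of mean index value with abundance."""

    accession: str
    per_species_r: Mapping[str, float]
    per_species_p: Mapping[str, float]
    mean_r: float


def aa_frequencies(sequence: str) -> np.ndarray:
    """Frequencies of the 20 standard residues in ``sequence``.

    Nonstandard residues are excluded from both numerator and denominator.
    Raises ``ValueError`` when no standard residue is present.
    """
    counts = np.zeros(20)
    for ch in sequence:
        i = _AA_INDEX.get(ch)
        if i is not None:
            counts[i] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("sequence contains no standard residues")
    return counts / total


def class_frequency_profile(dataset: ExpressionDataset) -> ClassFrequencyProfile:
    """Mean per-sequence frequency vectors for the high and low classes."""
    high = [e.sequence for e in dataset.entries if e.expr_class == "high"]
    low = [e.sequence for e in dataset.entries if e.expr_class == "low"]
    if not high or not low:
        raise ValueError("dataset must contain at least one high and one low entry")
    a_h = np.mean([aa_frequencies(s) for s in high], axis=0)
    a_l = np.mean([aa_frequencies(s) for s in low], axis=0)
    return ClassFrequencyProfile(a_h=a_h, a_l=a_l, n_high=len(high), n_low=len(low))


def compute_aei(dataset: ExpressionDataset) -> AEITable:
    """Amino-acid expression index: high-class mean frequency / low-class mean.

    A residue present in the high class but absent from the low class has an
    undefined (infinite) index and raises ``ValueError`` naming the residue —
    no silent pseudocount, since a dataset of realistic size never produces
    an all-absent residue.  A residue absent from *both* classes carries no
    bias information and is assigned the neutral value 1.
    """
    prof = class_frequency_profile(dataset)
    aei: dict[str, float] = {}
    for i, aa in enumerate(STANDARD_AA):
        if prof.a_l[i] == 0:
            if prof.a_h[i] == 0:
                aei[aa] = 1.0
                continue
            raise ValueError(
                f"AEI undefined: residue {aa} absent from the low-expression class"
            )
        aei[aa] = float(prof.a_h[i] / prof.a_l[i])
    return AEITable(species_id=dataset.species_id, aei=aei)


def compute_srab(sequence: str, aei_table: AEITable) -> SrabResult:
    """SRAB of ``sequence`` under ``aei_table``.

    ``exp( sum_i log(1 + AEI(a_i)) / (n - 1) )`` over the n standard residues
    in sequence order; nonstandard residues are skipped and excluded from n.
    """
    per_residue = tuple(aei_table[ch] for ch in sequence if ch in _AA_INDEX)
    n = len(per_residue)
    if n < 2:
        raise ValueError(f"SRAB requires >= 2 standard residues, got {n}")
    log_sum = sum(math.log1p(f) for f in per_residue)
    return SrabResult(
        value=math.exp(log_sum / (n - 1)), n_residues=n, per_residue_aei=per_residue
    )


def mean_biosynthetic_cost(sequence: str, cost_table: CostTable) -> float:
    """Arithmetic mean of per-residue ~P costs over standard residues."""
    costs = [cost_table[ch] for ch in sequence if ch in _AA_INDEX]
    if not costs:
        raise ValueError("sequence contains no standard residues")
    return float(np.mean(costs))


def cost_expression_analysis(
    dataset: ExpressionDataset, cost_table: CostTable
) -> dict[str, float | None]:
    """Spearman correlation of abundance with per-protein mean cost, plus class means.

    Returns keys ``spearman_r``, ``spearman_p`` (None when the correlation is
    undefined, e.g. constant costs), ``mean_cost_high``, ``mean_cost_low``.
    """
    if not dataset.entries:
        raise ValueError("empty dataset")
    costs = np.array([mean_biosynthetic_cost(e.sequence, cost_table) for e in dataset.entries])
    abundances = np.array([e.abundance for e in dataset.entries])
    classes = [e.expr_class for e in dataset.entries]
    out: dict[str, float | None] = {}
    if np.ptp(costs) == 0 or np.ptp(abundances) == 0:
        out["spearman_r"] = None
        out["spearman_p"] = None
    else:
        r, p = stats.spearmanr(abundances, costs)
        out["spearman_r"] = float(r)
        out["spearman_p"] = float(p)
    high = costs[[c == "high" for c in classes]]
    low = costs[[c == "low" for c in classes]]
    out["mean_cost_high"] = float(high.mean()) if high.size else None
    out["mean_cost_low"] = float(low.mean()) if low.size else None
    return out


def standardize_properties(indices: Sequence[PropertyIndex]) -> StandardizedPropertyMatrix:
    """Row-wise z-score the property matrix, ``Z = (X - mu) / sigma``.

    Population standard deviation (denominator 20).  Properties with missing
    values must be filtered out first; a constant row raises ``ValueError``
    naming the accession.
    """
    usable = [ix for ix in indices if not ix.has_missing]
    if len(usable) < len(indices):
        raise ValueError("standardize_properties received entries with missing values")
    if not usable:
        raise ValueError("no properties to standardize")
    X = np.array([[ix.values[aa] for aa in STANDARD_AA] for ix in usable], dtype=float)
    mu = X.mean(axis=1)
    sigma = X.std(axis=1)  # population sd, ddof=0
    for ix, s in zip(usable, sigma):
        if s == 0:
            raise ValueError(f"property {ix.accession} is constant; z-score undefined")
    Z = (X - mu[:, None]) / sigma[:, None]
    return StandardizedPropertyMatrix(
        accessions=tuple(ix.accession for ix in usable), raw=X, mu=mu, sigma=sigma, z=Z
    )


def mean_property_value(sequence: str, index: PropertyIndex) -> float:
    """Average index value over the standard residues of a sequence."""
    vals = [index.values[ch] for ch in sequence if ch in _AA_INDEX]
    if not vals:
        raise ValueError("sequence contains no standard residues")
    return float(np.mean(vals))


def property_expression_correlations(
    datasets: Sequence[ExpressionDataset], indices: Sequence[PropertyIndex]
) -> list[PropertyCorrelationResult]:
    """Correlate each AAindex property with expression across species.

    Per protein: mean index value over its residues.  Per species: Spearman
    correlation of that value against protein abundance.  Per property: the
    arithmetic mean of per-species correlations.  Properties with missing
    values, or whose correlation is undefined in every species, are skipped
    with a log entry.
    """
    results: list[PropertyCorrelationResult] = []
    for ix in indices:
        if ix.has_missing:
            logger.info("property %s skipped: missing values", ix.accession)
            continue
        per_r: dict[str, float] = {}
        per_p: dict[str, float] = {}
        for ds in datasets:
            if not ds.entries:
                raise ValueError(f"dataset {ds.species_id} is empty")
            vals = np.array([mean_property_value(e.sequence, ix) for e in ds.entries])
            abund = np.array([e.abundance for e in ds.entries])
            if np.ptp(vals) == 0 or np.ptp(abund) == 0:
                continue
            r, p = stats.spearmanr(abund, vals)
            per_r[ds.species_id] = float(r)
            per_p[ds.species_id] = float(p)
        if not per_r:
            logger.info("property %s skipped: correlation undefined in all species", ix.accession)
            continue
        results.append(
            PropertyCorrelationResult(
                accession=ix.accession,
                per_species_r=per_r,
                per_species_p=per_p,
                mean_r=float(np.mean(list(per_r.values()))),
            )
        )
    return results


def select_key_properties(
    results: Sequence[PropertyCorrelationResult], threshold: float = 0.2
) -> dict[str, object]:
    """Keep properties with ``|mean r| > threshold``; report sign counts."""
    kept = [r for r in results if abs(r.mean_r) > threshold]
    return {
        "kept": kept,
        "n_positive": sum(1 for r in kept if r.mean_r > 0),
        "n_negative": sum(1 for r in kept if r.mean_r < 0),
    }


def cluster_property_matrix(
    matrix: StandardizedPropertyMatrix,
) -> dict[str, str]:
    """Average-linkage hierarchical clustering of properties and of residues.

    Euclidean distance, deterministic leaf order.  Returns Newick strings
    under keys ``properties`` and ``residues``.
    """
    if matrix.z.shape[0] < 2:
        raise ValueError("need at least 2 property rows to cluster")
    out = {}
    out["properties"] = _linkage_to_newick(matrix.z, list(matrix.accessions))
    out["residues"] = _linkage_to_newick(matrix.z.T, list(STANDARD_AA))
    return out


def _linkage_to_newick(X: np.ndarray, labels: list[str]) -> str:
    link = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    tree = hierarchy.to_tree(link)

    def render(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        # deterministic child order: by (merge distance, rendered label)
        children = sorted([left, right])
        return f"({','.join(children)}):{length:.6g}"

    return render(tree, tree.dist) + ";"
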