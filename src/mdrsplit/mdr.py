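"""Core MDR machinery: cell tabulation, risk labeling, balanced accuracy,
and exhaustive search over locus combinations.

A k-locus combination partitions individuals into 3^k genotype cells.  A
cell is labeled high-risk when its case:control ratio exceeds the
threshold T = n1/n0 computed from the fitting data; the resulting binary
labeling is the MDR model for that combination.  Model quality is
balanced accuracy, BA = (sensitivity + specificity) / 2, which for
balanced data equals plain classification accuracy.

The search is vectorized: candidate combinations are processed in
chunks, with per-cell case/control counts for a whole chunk obtained
from a single ``bincount`` over offset cell indices.  High/low calls use
the integer cross-product form ``cases * n0 > controls * n1`` so that
empty cells (0 > 0 is false) and case-only cells (ratio +inf) fall out
of the same comparison, and equality at the threshold is low-risk.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .dataset import GenotypeDataset, InvalidGenotypeError

_CHUNK = 4096  # combinations per vectorized block; bounds peak memory


def encode_cell_index(genotype_codes) -> int:
    """Base-3 encode a k-tuple of genotype codes, first locus most significant.

    The 3^k genotype cells of a k-locus combination are indexed
    bijectively: ``(2, 1) -> 2*3 + 1 = 7``.
    """
    codes = tuple(int(c) for c in genotype_codes)
    if len(codes) < 1:
        raise ValueError("need at least one genotype code")
    idx = 0
    for c in codes:
        if c not in (0, 1, 2):
            raise InvalidGenotypeError(f"genotype code {c} outside {{0, 1, 2}}")
        idx = idx * 3 + c
    return idx


def decode_cell_index(index: int, k: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_cell_index`."""
    if not 0 <= index < 3**k:
        raise ValueError(f"cell index {index} out of range for k={k}")
    codes = []
    for _ in range(k):
        codes.append(index % 3)
        index //= 3
    return tuple(reversed(codes))


@dataclass(frozen=True)
class MDRModel:
    """High/low-risk labeling of the 3^k cells of one locus combination.

    ``cell_labels[c]`` is True when cell ``c`` is high-risk.
    ``cell_counts`` holds the fitting-data (cases, controls) pair per
    cell; ``threshold`` is the fitting-data case:control ratio n1/n0.
    """

    loci: tuple[int, ...]
    cell_labels: np.ndarray
    threshold: float
    cell_counts: np.ndarray

    @property
    def k(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class AccuracyResult:
    """Classification tallies and balanced accuracy of one evaluation."""

    n11: int  # cases classified as cases
    n00: int  # controls classified as controls
    n1: int
    n0: int

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.n11 / self.n1 + self.n00 / self.n0)

    @property
    def balanced_error(self) -> float:
        return 1.0 - self.balanced_accuracy


def _combo_matrix(n_loci: int, k: int, candidates=None) -> np.ndarray:
    """Candidate combinations as a (C, k) int array, lexicographic order."""
    if candidates is not None:
        combos = np.asarray([tuple(c) for c in candidates], dtype=np.int64)
        if combos.size == 0:
            raise ValueError("empty candidate list")
        if combos.ndim != 2 or combos.shape[1] != k:
            raise ValueError("candidate combinations must all have size k")
    else:
        if not 1 <= k <= n_loci:
            raise ValueError(f"model size k={k} outside [1, {n_loci}]")
        combos = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n_loci), k)),
            dtype=np.int64,
            count=comb(n_loci, k) * k,
        ).reshape(-1, k)
    if (combos < 0).any() or (combos >= n_loci).any():
        raise IndexError("locus index out of range")
    return combos


def _cell_index_matrix(genotypes: np.ndarray, combos: np.ndarray) -> np.ndarray:
    """(n, C) matrix of base-3 cell indices; first locus most significant."""
    k = combos.shape[1]
    idx = genotypes[:, combos[:, 0]].astype(np.int64)
    for j in range(1, k):
        idx = idx * 3 + genotypes[:, combos[:, j]]
    return idx


def _tabulate(data: GenotypeDataset, combos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell (cases, controls) counts for every combination in a chunk.

    Returns two (C, 3^k) arrays.
    """
    n_cells = 3 ** combos.shape[1]
    idx = _cell_index_matrix(data.genotypes, combos)
    offset = np.arange(combos.shape[0], dtype=np.int64) * n_cells
    flat = idx + offset  # broadcast over rows
    is_case = data.phenotype.astype(bool)
    minlength = combos.shape[0] * n_cells
    case_counts = np.bincount(flat[is_case].ravel(), minlength=minlength)
    ctrl_counts = np.bincount(flat[~is_case].ravel(), minlength=minlength)
    return (
        case_counts.reshape(-1, n_cells),
        ctrl_counts.reshape(-1, n_cells),
    )


def _labels(case_counts: np.ndarray, ctrl_counts: np.ndarray, n1: int, n0: int) -> np.ndarray:
    """High-risk mask: cases/controls > n1/n0, in exact integer arithmetic."""
    return case_counts * n0 > ctrl_counts * n1


def _ba_from_counts(
    labels: np.ndarray, case_counts: np.ndarray, ctrl_counts: np.ndarray, n1: int, n0: int
) -> np.ndarray:
    n11 = np.where(labels, case_counts, 0).sum(axis=1)
    n00 = np.where(labels, 0, ctrl_counts).sum(axis=1)
    return 0.5 * (n11 / n1 + n00 / n0)


def fit_risk_model(data: GenotypeDataset, loci) -> MDRModel:
    """Fit the MDR high/low-risk labeling for one locus combination.

    Each cell is labeled high-risk iff its case:control ratio strictly
    exceeds n1/n0 of the fitting data.  Empty cells and ties are
    low-risk; cells with cases but no controls are high-risk.
    """
    data.require_both_classes()
    loci = tuple(int(i) for i in loci)
    combos = _combo_matrix(data.n_loci, len(loci), candidates=[loci])
    case_counts, ctrl_counts = _tabulate(data, combos)
    labels = _labels(case_counts, ctrl_counts, data.n_cases, data.n_controls)
    counts = np.stack([case_counts[0], ctrl_counts[0]], axis=1)
    return MDRModel(
        loci=loci,
        cell_labels=labels[0],
        threshold=data.n_cases / data.n_controls,
        cell_counts=counts,
    )


def balanced_accuracy(model: MDRModel, data: GenotypeDataset) -> AccuracyResult:
    """Evaluate a fitted model's balanced accuracy on (possibly new) data.

    Cells unseen at fitting time carry the low-risk label, so no special
    handling is needed at evaluation.
    """
    data.require_both_classes()
    combos = np.asarray([model.loci], dtype=np.int64)
    case_counts, ctrl_counts = _tabulate(data, combos)
    high = model.cell_labels
    n11 = int(np.where(high, case_counts[0], 0).sum())
    n00 = int(np.where(high, 0, ctrl_counts[0]).sum())
    return AccuracyResult(n11=n11, n00=n00, n1=data.n_cases, n0=data.n_controls)


def _search_scores(
    data: GenotypeDataset, k: int, candidates=None
) -> tuple[np.ndarray, np.ndarray]:
    """BA of every candidate k-combination on ``data`` (fit == eval set).

    Returns (combos, ba) with combos in lexicographic order, the basis
    for all deterministic tie-breaking downstream.
    """
    data.require_both_classes()
    combos = _combo_matrix(data.n_loci, k, candidates)
    n1, n0 = data.n_cases, data.n_controls
    out = np.empty(combos.shape[0])
    for start in range(0, combos.shape[0], _CHUNK):
        chunk = combos[start : start + _CHUNK]
        case_counts, ctrl_counts = _tabulate(data, chunk)
        labels = _labels(case_counts, ctrl_counts, n1, n0)
        out[start : start + _CHUNK] = _ba_from_counts(labels, case_counts, ctrl_counts, n1, n0)
    return combos, out


def rank_models_for_k(data: GenotypeDataset, k: int, x: int, candidates=None):
    """Top-x combinations of size k by fitting-set BA, descending.

    Ties are resolved toward the lexicographically smallest locus
    tuple, making the ranking fully deterministic.

    Returns a list of ``(loci_tuple, ba)`` of length ``min(x, C)``.
    """
    if x < 1:
        raise ValueError("x must be >= 1")
    combos, ba = _search_scores(data, k, candidates)
    # stable sort on -ba keeps lexicographic order among exact ties
    order = np.argsort(-ba, kind="stable")[:x]
    return [(tuple(int(i) for i in combos[j]), float(ba[j])) for j in order]


def best_model_for_k(data: GenotypeDataset, k: int, candidates=None):
    """Exhaustive (or candidate-restricted) search for the BA-best model.

    Returns ``(MDRModel, AccuracyResult)`` for the winning combination,
    refit on the full ``data``.
    """
    (loci, _),  = rank_models_for_k(data, k, 1, candidates)
    model = fit_risk_model(data, loci)
    return model, balanced_accuracy(model, data)


def count_combinations(n_loci: int, k: int) -> int:
    """C(K, k): the exhaustive-search workload for size k."""
    return comb(n_loci, k)
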