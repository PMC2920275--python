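"""Post-hoc pruning of an MDR model by backward-selection logistic regression.

The selected loci are expanded into genotype indicator variables (two
dummies per locus — heterozygote and minor homozygote, with the common
homozygote as reference) so no mode of inheritance is assumed, and the
full model contains every interaction among the loci: a term of s loci
contributes the 2^s products of its per-locus indicators.  Backward
selection then removes whole terms, either while their likelihood-ratio
p-value exceeds a preset threshold or while removal lowers AIC/BIC.
The pruned model is the union of loci referenced by surviving terms;
it may be empty.

Fitting uses statsmodels maximum likelihood with a ridge-stabilized
fallback for separated or rank-deficient designs, which the sparse
3^k cell structure produces routinely.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.linalg import qr
from scipy.stats import chi2

from .dataset import GenotypeDataset

_RIDGE_ALPHA = 1e-4


@dataclass(frozen=True)
class PruningConfig:
    """Backward-selection settings.

    criterion is ``"aic"``, ``"bic"`` or ``"p_threshold"``; p_cut is the
    retention threshold for the latter (conventional sweeps run it from
    0.1 down to 1e-7).  max_order caps interaction order in the full
    model (default: all orders).  group_terms=False switches the
    removal unit from whole terms to single indicator columns.
    """

    criterion: str = "bic"
    p_cut: float = 0.05
    max_order: int | None = None
    group_terms: bool = True

    def __post_init__(self) -> None:
        if self.criterion not in ("aic", "bic", "p_threshold"):
            raise ValueError("criterion must be 'aic', 'bic' or 'p_threshold'")
        if self.criterion == "p_threshold" and not 0.0 < self.p_cut < 1.0:
            raise ValueError("p_cut must lie in (0, 1)")


@dataclass(frozen=True)
class TermSet:
    """Surviving model terms; each term is a tuple of locus indices."""

    terms: frozenset

    @property
    def surviving_loci(self) -> frozenset:
        return frozenset(itertools.chain.from_iterable(self.terms))


@dataclass(frozen=True)
class FullDesign:
    """Design matrix for the saturated genotype-indicator model."""

    loci: tuple[int, ...]
    terms: tuple[tuple[int, ...], ...]
    X: np.ndarray                      # (n, p), no intercept column
    term_columns: dict = field(hash=False)  # term -> column index list
    column_names: tuple[str, ...] = ()


def build_full_design(data: GenotypeDataset, loci, max_order: int | None = None) -> FullDesign:
    """Expand ``loci`` into the all-interactions indicator design.

    Terms are the non-empty subsets of ``loci`` up to ``max_order``; a
    size-s term expands to 2^s product columns.
    """
    loci = tuple(sorted(int(i) for i in loci))
    if not loci:
        raise ValueError("need at least one locus")
    order = len(loci) if max_order is None else min(max_order, len(loci))
    indicators = {}
    for j in loci:
        g = data.genotypes[:, j]
        indicators[j] = ((g == 1).astype(float), (g == 2).astype(float))

    terms: list[tuple[int, ...]] = []
    for s in range(1, order + 1):
        terms.extend(itertools.combinations(loci, s))

    cols: list[np.ndarray] = []
    names: list[str] = []
    term_columns: dict = {}
    for term in terms:
        idxs = []
        for choice in itertools.product((1, 2), repeat=len(term)):
            col = np.ones(data.n)
            for j, lvl in zip(term, choice):
                col = col * indicators[j][lvl - 1]
            idxs.append(len(cols))
            cols.append(col)
            names.append("*".join(f"{data.locus_names[j]}[{lvl}]" for j, lvl in zip(term, choice)))
        term_columns[term] = idxs
    X = np.column_stack(cols) if cols else np.empty((data.n, 0))
    return FullDesign(loci=loci, terms=tuple(terms), X=X,
                      term_columns=term_columns, column_names=tuple(names))


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Log-likelihood and parameter count of a logistic fit.

    Collinear/empty columns are dropped by pivoted QR before fitting;
    separation or non-convergence falls back to a ridge-penalized GLM
    whose likelihood is evaluated at the penalized estimate.
    """
    n = y.shape[0]
    if X.shape[1] == 0:
        p = y.mean()
        ll = 0.0 if p in (0.0, 1.0) else n * (p * np.log(p) + (1 - p) * np.log(1 - p))
        return float(ll), 1
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    Xr = X[:, piv[:rank]] if rank else np.empty((n, 0))
    if Xr.shape[1] == 0:
        return _fit_logit(y, Xr)
    X1 = sm.add_constant(Xr, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X1).fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.isfinite(res.llf):
                return float(res.llf), rank + 1
        except Exception:
            pass
        # ridge-stabilized fallback: small L2 penalty guarantees a finite fit
        glm = sm.GLM(y, X1, family=sm.families.Binomial())
        try:
            res = glm.fit_regularized(alpha=_RIDGE_ALPHA, L1_wt=0.0)
            eta = X1 @ np.asarray(res.params)
        except Exception:
            eta = np.zeros(n)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return ll, rank + 1


def backward_select(data: GenotypeDataset, design: FullDesign, config: PruningConfig) -> TermSet:
    """Greedy backward elimination over the design's terms.

    p_threshold: repeatedly drop the term with the largest
    likelihood-ratio p-value while it exceeds p_cut.  aic/bic:
    repeatedly apply the single removal that most decreases the
    criterion.  Removal candidates are scanned largest-term-first, then
    lexicographically, which fixes all tie-breaking.
    """
    y = data.phenotype.astype(float)
    if config.group_terms:
        units = [(term, design.term_columns[term]) for term in design.terms]
    else:
        units = [
            ((term, c), [c])
            for term in design.terms
            for c in design.term_columns[term]
        ]
    units.sort(key=lambda u: (-len(u[1]), u[0]))

    def fit_units(active) -> tuple[float, int]:
        cols = [c for _, cs in active for c in cs]
        return _fit_logit(y, design.X[:, cols])

    penalty = {"aic": 2.0, "bic": float(np.log(data.n))}.get(config.criterion)

    active = list(units)
    while active:
        ll_full, df_full = fit_units(active)
        if config.criterion == "p_threshold":
            worst, worst_p = None, -1.0
            for unit in active:
                reduced = [u for u in active if u is not unit]
                ll_red, df_red = fit_units(reduced)
                ddf = df_full - df_red
                if ddf <= 0:
                    p = 1.0  # degenerate term: contributes nothing, removable
                else:
                    stat = max(2.0 * (ll_full - ll_red), 0.0)
                    p = float(chi2.sf(stat, ddf))
                if p > worst_p:
                    worst, worst_p = unit, p
            if worst_p > config.p_cut:
                active.remove(worst)
            else:
                break
        else:
            crit_full = -2.0 * ll_full + penalty * df_full
            best, best_crit = None, crit_full
            for unit in active:
                reduced = [u for u in active if u is not unit]
                ll_red, df_red = fit_units(reduced)
                crit = -2.0 * ll_red + penalty * df_red
                if crit < best_crit:
                    best, best_crit = unit, crit
            if best is not None:
                active.remove(best)
            else:
                break

    if config.group_terms:
        surviving = frozenset(term for term, _ in active)
    else:
        surviving = frozenset(term for (term, _c), _ in active)
    return TermSet(terms=surviving)


def prune_model(data: GenotypeDataset, loci, config: PruningConfig) -> frozenset:
    """Prune an MDR-selected locus set on the entire dataset.

    Returns the loci involved in the surviving terms; an empty set
    means no term survived (distinct from a one-locus model).
    """
    design = build_full_design(data, loci, config.max_order)
    return backward_select(data, design, config).surviving_loci
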