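"""Effect sizes, multiplicity adjustment and redundancy checks.

The per-sample distance score D is computed without reference to the
sample's own label, so it can legitimately enter a logistic regression of
case status; exp(slope) is then the increase in odds per unit D.  Pathways
probing the same SNPs are culled greedily by pairwise SNP overlap, and the
correlation of D vectors across pathways flags pathways whose signal tracks
the same samples.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from poda.errors import ValidationError
from poda.io import PhenotypeVector

logger = logging.getLogger("poda")


@dataclass
class LogisticEffect:
    odds_ratio: float
    p_value: float
    slope: float
    separated: bool = False
    converged: bool = True

    def __iter__(self):  # allow `OR, p = logistic_odds_ratio(...)`
        return iter((self.odds_ratio, self.p_value))


def logistic_odds_ratio(D: np.ndarray, phenotypes: PhenotypeVector) -> LogisticEffect:
    """Fit status ~ intercept + D by maximum likelihood; OR = exp(slope).

    Perfect separation is reported via the ``separated`` flag (with the
    diverging estimate as fitted) rather than through a penalized fit, to
    keep plain-logistic semantics.
    """
    D = np.asarray(D, dtype=float)
    y = phenotypes.is_case.astype(float)
    if not np.isfinite(D).all():
        raise ValidationError("non-finite D values in logistic fit")
    if y.min() == y.max():
        raise ValidationError("both classes must be present")
    if np.ptp(D) == 0:
        # a constant regressor carries no information: slope 0, OR 1
        return LogisticEffect(1.0, 1.0, 0.0)
    X = sm.add_constant(D)
    separated = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except Exception as exc:  # statsmodels raises on hard separation
            logger.warning("logistic fit failed (%s); flagging separation", exc)
            slope = np.sign(np.corrcoef(D, y)[0, 1]) * np.inf
            return LogisticEffect(np.exp(slope), 0.0, slope, separated=True, converged=False)
        for w in caught:
            if "separat" in str(w.message).lower():
                separated = True
    converged = bool(fit.mle_retvals.get("converged", True))
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    fitted = fit.predict(X)
    if not separated:
        separated = bool(np.all(np.abs(fitted - y) < 1e-3))
    if separated:
        logger.warning("perfect separation detected in logistic fit")
    return LogisticEffect(float(np.exp(slope)), p, slope, separated, converged)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("p_values must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CullingReport:
    retained: list[str]
    removed: dict[str, str]  # removed pathway -> retained partner that triggered it
    order_outcomes: list[frozenset]
    modal_frequency: float
    threshold: float


def _overlap_fraction(a: set, b: set, denominator: str) -> float:
    shared = len(a & b)
    if denominator == "min":
        return shared / min(len(a), len(b))
    if denominator == "first":
        return shared / len(a)
    raise ValidationError(f"unknown overlap denominator {denominator!r}")


def _greedy_cull(ids, sets, order, threshold, denominator):
    retained: list[str] = []
    removed: dict[str, str] = {}
    for pid in order:
        partner = None
        for r in retained:
            if _overlap_fraction(sets[pid], sets[r], denominator) > threshold:
                partner = r
                break
        if partner is None:
            retained.append(pid)
        else:
            removed[pid] = partner
    return retained, removed


def pathway_overlap_cull(
    selections,
    scores: dict[str, float],
    threshold: float = 0.60,
    n_orders: int = 25,
    seed: int | None = 0,
    denominator: str = "min",
) -> CullingReport:
    """Greedily drop pathways sharing more than ``threshold`` of their SNPs.

    ``selections`` maps pathway id -> SnpSelection (or any object with
    ``snp_ids``).  A pathway is removed when it shares strictly more than the
    threshold fraction (shared / size of the smaller set by default) with an
    already-retained pathway.  Because the outcome depends on the scan order,
    the pass is repeated over ``n_orders`` random orders plus the
    score-descending order, and the modal retained set is returned (ties
    resolved toward the score-descending outcome).
    """
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0, 1)")
    ids = sorted(selections)
    sets = {pid: set(selections[pid].snp_ids) for pid in ids}
    by_score = sorted(ids, key=lambda p: (-scores.get(p, 0.0), p))
    rng = np.random.default_rng(seed)
    orders = [by_score] + [list(rng.permutation(ids)) for _ in range(n_orders)]
    outcomes = []
    details = {}
    for order in orders:
        retained, removed = _greedy_cull(ids, sets, order, threshold, denominator)
        key = frozenset(retained)
        outcomes.append(key)
        details.setdefault(key, (retained, removed))
    counts = Counter(outcomes)
    top = max(counts.values())
    modal_keys = [k for k, c in counts.items() if c == top]
    key = outcomes[0] if outcomes[0] in modal_keys else modal_keys[0]
    retained, removed = details[key]
    # report retained in score order for readability
    retained = [p for p in by_score if p in key]
    return CullingReport(retained, removed, outcomes, top / len(orders), threshold)


def d_correlation_matrix(profiles) -> np.ndarray:
    """Pearson correlation of per-sample D vectors across pathways.

    Zero-variance profiles yield nan entries (flagged with a warning) rather
    than a silent zero; the diagonal is exactly 1.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    samples = profiles[0].sample_ids
    for p in profiles[1:]:
        if p.sample_ids != samples:
            raise ValidationError("profiles cover different samples")
    X = np.array([p.D for p in profiles])
    sd = X.std(axis=1)
    if np.any(sd == 0):
        logger.warning("zero-variance D profile(s); correlation entries set to nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    np.fill_diagonal(corr, 1.0)
    for i, s in enumerate(sd):
        if s == 0:
            corr[i, :] = np.nan
            corr[:, i] = np.nan
            corr[i, i] = 1.0
    return corr
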