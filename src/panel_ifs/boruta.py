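"""All-relevant feature filtering with shadow features (Boruta).

Each iteration (1) appends an independently permuted "shadow" copy of every
still-undecided feature to the matrix, (2) fits a random-forest classifier
and reads its mean-decrease-impurity importances, and (3) records a "hit"
for every undecided feature whose importance exceeds the maximum shadow
importance.  After each iteration a two-sided binomial test against the
fair-coin null (hit probability 1/2), Bonferroni-corrected across all
input features, confirms features with significantly many hits and rejects
features with significantly few.  The loop stops when nothing is undecided
or after ``max_iter`` iterations; survivors are resolved by the median
"rough fix": an undecided feature is kept as weakly-supported tentative iff
its median importance across iterations exceeds the median of the
per-iteration maximum shadow importances, and rejected otherwise.  The
pipeline's retained set is confirmed plus tentative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .dataio import ExpressionDataset

__all__ = ["BorutaResult", "make_shadow_features", "binomial_decision", "run_boruta"]

DEFAULT_RF_PARAMS = {"n_estimators": 500}


@dataclass
class BorutaResult:
    """Outcome of a Boruta run; the three sets partition the input genes."""

    confirmed: set[str]
    rejected: set[str]
    tentative: set[str]
    hit_counts: dict[str, int]
    n_iterations: int

    @property
    def retained(self) -> set[str]:
        """Definite gene set fed downstream: confirmed plus weak tentative."""
        return self.confirmed | self.tentative


def make_shadow_features(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """[original | shadow] matrix; each shadow column is an independent
    permutation of its source column."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise ValueError("values must be a nonempty 2-D matrix")
    shadow = values.copy()
    for j in range(shadow.shape[1]):
        rng.shuffle(shadow[:, j])
    return np.hstack([values, shadow])


def binomial_decision(
    hits: int, trials: int, alpha: float, n_features: int
) -> str:
    """'confirmed', 'rejected' or 'tentative' from the hit count.

    Upper-tail binomial(trials, 1/2) p-value below the Bonferroni-corrected
    alpha confirms; lower-tail below it rejects; otherwise tentative.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if trials < 1 or not 0 <= hits <= trials:
        raise ValueError(f"need 0 <= hits <= trials, trials >= 1; got {hits}/{trials}")
    corrected = alpha / max(n_features, 1)
    p_upper = stats.binom.sf(hits - 1, trials, 0.5)
    p_lower = stats.binom.cdf(hits, trials, 0.5)
    if p_upper < corrected:
        return "confirmed"
    if p_lower < corrected:
        return "rejected"
    return "tentative"


def run_boruta(
    dataset: ExpressionDataset,
    max_iter: int = 100,
    alpha: float = 0.05,
    rf_params: dict | None = None,
    seed: int = 0,
) -> BorutaResult:
    """Run the shadow-feature filter on a labeled dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
        Must contain at least two classes.
    max_iter : int
        Maximum number of shadow/fit/test iterations.
    alpha : float
        Per-test significance level before Bonferroni correction.
    rf_params : dict, optional
        Overrides for the random forest (default: 500 trees, scikit-learn
        defaults otherwise).
    seed : int
        Drives both the shadow permutations and the forests.

    Notes
    -----
    Every iteration shadows the full original matrix, so the shadow
    maximum is always the maximum over all m permuted columns; a weaker
    null from a shrinking shadow pool would let late-surviving noise
    features accumulate spurious hits.  Decided features simply stop being
    tested.
    """
    if dataset.n_classes < 2 or len(np.unique(dataset.labels)) < 2:
        raise ValueError("Boruta requires at least two classes")
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    params = dict(DEFAULT_RF_PARAMS)
    if rf_params:
        params.update(rf_params)

    rng = np.random.default_rng(seed)
    m = dataset.n_genes
    genes = list(dataset.gene_ids)
    status = np.full(m, "tentative", dtype=object)
    hits = np.zeros(m, dtype=int)
    trials = 0
    imp_history: list[np.ndarray] = []  # per-iteration real-feature importances
    shadow_max_history: list[float] = []

    for _ in range(max_iter):
        undecided = status == "tentative"
        if not undecided.any():
            break
        X = make_shadow_features(dataset.values, rng)
        forest = RandomForestClassifier(
            random_state=int(rng.integers(0, 2**31 - 1)), **params
        )
        forest.fit(X, dataset.labels)
        imp = forest.feature_importances_
        real_imp, shadow_imp = imp[:m], imp[m:]
        shadow_max = float(shadow_imp.max())
        shadow_max_history.append(shadow_max)
        imp_history.append(real_imp)

        trials += 1
        hits[undecided & (real_imp > shadow_max)] += 1

        # Bonferroni across ALL input features: a correction that shrinks
        # with the undecided count turns anticonservative once only a few
        # stragglers remain (a lone survivor would face raw alpha).
        for j in np.flatnonzero(undecided):
            status[j] = binomial_decision(int(hits[j]), trials, alpha, m)

    # median rough fix for whatever is still undecided at max_iter: keep a
    # feature as (weak) tentative if its median importance beats the median
    # of the max-shadow importances, otherwise reject it.  Undecided
    # features never enter `confirmed`; that set stays strictly the
    # binomial-test survivors.
    confirmed, rejected, tentative = set(), set(), set()
    if imp_history:
        median_shadow = float(np.median(shadow_max_history))
        imp_matrix = np.vstack(imp_history)
    for j, g in enumerate(genes):
        if status[j] == "confirmed":
            confirmed.add(g)
        elif status[j] == "rejected":
            rejected.add(g)
        else:
            med = float(np.median(imp_matrix[:, j]))
            (tentative if med > median_shadow else rejected).add(g)

    return BorutaResult(
        confirmed=confirmed,
        rejected=rejected,
        tentative=tentative,
        hit_counts={g: int(hits[j]) for j, g in enumerate(genes)},
        n_iterations=trials,
    )
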