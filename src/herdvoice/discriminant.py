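"""Stepwise linear discriminant function analysis (DFA).

Implements the classical SPSS-style workflow for vocal-individuality
analysis: Wilks'-lambda stepwise variable selection (F-to-enter 3.84,
F-to-remove 2.71), canonical discriminant functions from the
eigen-decomposition of W⁻¹B, Fisher linear classification with group-size
priors, resubstitution / leave-one-out / transfer classification reports,
and exact two-tailed binomial tests of correct-classification counts against
the group-size chance expectation 100/g %.

Group means and scatter matrices are computed once; Wilks' lambda for any
variable subset is then a ratio of sub-determinants, which keeps the
stepwise search and leave-one-out loop fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st

log = logging.getLogger(__name__)

F_ENTER_DEFAULT = 3.84
F_REMOVE_DEFAULT = 2.71


class DFAError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scatter matrices and Wilks' lambda
# ---------------------------------------------------------------------------

def _design(table: pd.DataFrame, variables: list[str],
            group_col: str = "individual_id",
            ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    X = table[list(variables)].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise DFAError("feature table contains missing values; "
                       "drop incomplete rows first")
    g = table[group_col].to_numpy()
    groups = sorted(pd.unique(g).tolist())
    y = np.array([groups.index(v) for v in g])
    return X, y, groups


def scatter_matrices(X: np.ndarray, y: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                np.ndarray]:
    """Within-group (W), total (T) cross-products, group means, counts."""
    n, p = X.shape
    groups = np.unique(y)
    means = np.vstack([X[y == k].mean(axis=0) for k in groups])
    counts = np.array([(y == k).sum() for k in groups])
    grand = X.mean(axis=0)
    Xc = X - grand
    T = Xc.T @ Xc
    W = np.zeros((p, p))
    for i, k in enumerate(groups):
        d = X[y == k] - means[i]
        W += d.T @ d
    return W, T, means, counts


def wilks_lambda(table: pd.DataFrame, variables: list[str],
                 group_col: str = "individual_id") -> float:
    """Λ = det(W)/det(T) over the chosen variables."""
    X, y, groups = _design(table, variables, group_col)
    _check_dims(X, y, groups, variables)
    W, T, _, _ = scatter_matrices(X, y)
    return _lambda_from_scatter(W, T, list(range(len(variables))),
                                variables)


def _check_dims(X, y, groups, variables) -> None:
    if len(groups) < 2:
        raise DFAError("need at least 2 groups")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise DFAError("every group needs at least 2 rows")
    if X.shape[0] <= len(variables) + len(groups):
        raise DFAError("too few rows for this many variables and groups")


def _lambda_from_scatter(W: np.ndarray, T: np.ndarray, cols: list[int],
                         names: list[str] | None = None) -> float:
    Wc = W[np.ix_(cols, cols)]
    Tc = T[np.ix_(cols, cols)]
    sign_t, logdet_t = np.linalg.slogdet(Tc)
    if sign_t <= 0 or logdet_t < -600:
        bad = names if names else cols
        raise DFAError(f"singular total scatter matrix; collinear "
                       f"variables among {bad}")
    sign_w, logdet_w = np.linalg.slogdet(Wc)
    if sign_w <= 0:
        return 0.0
    return float(np.clip(np.exp(logdet_w - logdet_t), 0.0, 1.0))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    steps: list[tuple[int, str, str, float, float]]  # (#, action, var, F, Λ)
    selected: list[str]
    f_enter: float
    f_remove: float


def _partial_f(lam_old: float, lam_new: float, n: int, g: int,
               p_in: int) -> float:
    """F statistic for the change in Wilks' lambda when adding one variable
    to ``p_in`` already-entered variables."""
    if lam_new <= 0:
        return np.inf
    return (lam_old / lam_new - 1.0) * (n - g - p_in) / (g - 1)


def stepwise_select(table: pd.DataFrame, variables: list[str] | None = None,
                    f_enter: float = F_ENTER_DEFAULT,
                    f_remove: float = F_REMOVE_DEFAULT,
                    group_col: str = "individual_id",
                    max_steps: int = 100) -> StepwiseResult:
    """Wilks'-lambda stepwise variable selection.

    At each step the excluded variable with the largest partial F enters if
    F >= f_enter; afterwards any included variable whose partial F (for
    removal) has dropped below f_remove leaves.  Ties break lexicographically
    (logged).  Terminates when no entry or removal qualifies.
    """
    from .params import PARAM_NAMES
    if variables is None:
        variables = [c for c in PARAM_NAMES if c in table.columns]
    X, y, groups = _design(table, variables, group_col)
    n, g = len(y), len(groups)
    W, T, _, _ = scatter_matrices(X, y)
    included: list[int] = []
    steps: list[tuple[int, str, str, float, float]] = []
    lam_cur = 1.0
    step_no = 0
    for _ in range(max_steps):
        # --- entry
        best_j, best_f, best_lam = None, -np.inf, None
        for j in range(len(variables)):
            if j in included:
                continue
            try:
                lam = _lambda_from_scatter(W, T, included + [j])
            except DFAError:
                continue
            fj = _partial_f(lam_cur, lam, n, g, len(included))
            if fj > best_f + 1e-12 or (
                    abs(fj - best_f) <= 1e-12 and best_j is not None
                    and variables[j] < variables[best_j]):
                if abs(fj - best_f) <= 1e-12:
                    log.info("stepwise tie at F=%.4f; choosing %s "
                             "lexicographically", fj, variables[j])
                best_j, best_f, best_lam = j, fj, lam
        entered = False
        if best_j is not None and best_f >= f_enter:
            included.append(best_j)
            lam_cur = best_lam
            step_no += 1
            steps.append((step_no, "enter", variables[best_j],
                          float(best_f), lam_cur))
            entered = True
        # --- removal sweep
        removed = True
        while removed and len(included) > 1:
            removed = False
            worst_j, worst_f = None, np.inf
            for j in included:
                rest = [k for k in included if k != j]
                lam_rest = _lambda_from_scatter(W, T, rest)
                fj = _partial_f(lam_rest, lam_cur, n, g, len(rest))
                if fj < worst_f:
                    worst_j, worst_f = j, fj
            if worst_j is not None and worst_f < f_remove:
                included.remove(worst_j)
                lam_cur = _lambda_from_scatter(W, T, included)
                step_no += 1
                steps.append((step_no, "remove", variables[worst_j],
                              float(worst_f), lam_cur))
                removed = True
        if not entered and not removed:
            break
    if not included:
        log.warning("no variable met the entry criterion F >= %.2f",
                    f_enter)
    return StepwiseResult(steps=steps,
                          selected=[variables[j] for j in included],
                          f_enter=f_enter, f_remove=f_remove)


# ---------------------------------------------------------------------------
# canonical DFA model
# ---------------------------------------------------------------------------

@dataclass
class DFAModel:
    groups: list[str]
    variables: list[str]
    group_means: np.ndarray          # g x p
    pooled_cov: np.ndarray           # p x p, W / (n - g)
    priors: np.ndarray               # g
    eigenvalues: np.ndarray          # per canonical function
    coeffs_raw: np.ndarray           # p x n_func
    coeffs_std: np.ndarray           # p x n_func
    const_raw: np.ndarray            # per function (centering constants)
    function_tests: list[dict]       # Bartlett chi-square per function
    n_train: int = 0

    def scores(self, rows: pd.DataFrame) -> np.ndarray:
        """Canonical discriminant scores (rows x functions)."""
        X = rows[self.variables].to_numpy(float)
        return X @ self.coeffs_raw + self.const_raw


def fit_dfa(table: pd.DataFrame, variables: list[str],
            group_col: str = "individual_id",
            priors: np.ndarray | str = "proportional") -> DFAModel:
    """Canonical discriminant functions from the eigenproblem W⁻¹B.

    Raw coefficients are scaled so canonical scores have unit pooled
    within-group variance; standardized coefficients multiply the raw ones by
    the pooled within-group SD of each variable.  Function significance uses
    Bartlett's chi-square on the residual Wilks' lambda after removing the
    leading functions.
    """
    if not variables:
        raise DFAError("no variables selected")
    X, y, groups = _design(table, variables, group_col)
    _check_dims(X, y, groups, variables)
    n, p = X.shape
    g = len(groups)
    W, T, means, counts = scatter_matrices(X, y)
    B = T - W
    try:
        WinvB = np.linalg.solve(W, B)
    except np.linalg.LinAlgError as err:
        raise DFAError("singular pooled within-group matrix; reduce the "
                       "variable set") from err
    evals, evecs = np.linalg.eig(WinvB)
    order = np.argsort(-evals.real)
    n_func = min(p, g - 1)
    evals = evals.real[order][:n_func]
    A = evecs.real[:, order][:, :n_func]
    pooled = W / (n - g)
    # unit pooled within-group variance of each canonical score
    scale = np.sqrt(np.einsum("ij,jk,ki->i", A.T, pooled, A))
    A = A / scale
    grand = X.mean(axis=0)
    const = -(grand @ A)
    std = np.sqrt(np.diag(pooled))
    coeffs_std = A * std[:, None]

    tests = []
    lam_resid = np.cumprod((1.0 / (1.0 + evals))[::-1])[::-1]
    for k in range(n_func):
        lam_k = float(lam_resid[k])
        chi2 = -(n - 1 - (p + g) / 2.0) * np.log(max(lam_k, 1e-300))
        df = (p - k) * (g - 1 - k)
        tests.append({"function": k + 1, "wilks_lambda": lam_k,
                      "chi_square": float(chi2), "df": int(df),
                      "p_value": float(st.chi2.sf(chi2, df))})

    if isinstance(priors, str):
        pri = (counts / n if priors == "proportional"
               else np.full(g, 1.0 / g))
    else:
        pri = np.asarray(priors, float)
        pri = pri / pri.sum()
    return DFAModel(groups=groups, variables=list(variables),
                    group_means=means, pooled_cov=pooled, priors=pri,
                    eigenvalues=evals, coeffs_raw=A, coeffs_std=coeffs_std,
                    const_raw=const, function_tests=tests, n_train=n)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    mode: str                        # resubstitution | loo | transfer
    groups: list[str]
    confusion: np.ndarray            # true x assigned counts
    n: int
    n_skipped: int = 0

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.confusion))

    @property
    def percent_correct(self) -> float:
        """Overall % correct weighted by the actual group sizes
        (total correct / total classified)."""
        return 100.0 * self.n_correct / self.n

    @property
    def per_group_correct(self) -> np.ndarray:
        rows = self.confusion.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * np.diag(self.confusion) / rows


def _fisher_scores(X: np.ndarray, means: np.ndarray, pooled: np.ndarray,
                   priors: np.ndarray) -> np.ndarray:
    """Linear classification scores gᵀΣ⁻¹x − ½gᵀΣ⁻¹g + ln prior.

    Uses a pseudo-inverse so that rank-deficient pooled scatter (possible in
    tiny leave-one-out folds) degrades gracefully instead of blowing up.
    """
    Sm = np.linalg.pinv(pooled, hermitian=True,
                        rcond=1e-10) @ means.T   # p x g
    lin = X @ Sm                                     # n x g
    const = -0.5 * np.einsum("ij,ji->i", means, Sm) \
        + np.log(np.maximum(priors, 1e-300))
    return lin + const


def classify(model: DFAModel, rows: pd.DataFrame,
             mode: str = "resubstitution",
             group_col: str = "individual_id") -> ClassificationReport:
    """Assign each row to the group with the highest linear classification
    score; ties go to the lowest group index (logged)."""
    g = len(model.groups)
    conf = np.zeros((g, g), int)
    missing = [v for v in model.variables if v not in rows.columns]
    if missing:
        raise DFAError(f"rows lack model variables {missing}")
    sub = rows.dropna(subset=list(model.variables))
    n_skipped = len(rows) - len(sub)
    if n_skipped:
        log.warning("%d rows skipped for missing variables", n_skipped)
    X = sub[model.variables].to_numpy(float)
    scores = _fisher_scores(X, model.group_means, model.pooled_cov,
                            model.priors)
    assigned = np.argmax(scores, axis=1)   # argmax takes lowest index on ties
    truth = sub[group_col].to_numpy()
    for t, a in zip(truth, assigned):
        if t in model.groups:
            conf[model.groups.index(t), a] += 1
    return ClassificationReport(mode=mode, groups=model.groups,
                                confusion=conf, n=int(conf.sum()),
                                n_skipped=n_skipped)


def loo_crossvalidate(table: pd.DataFrame, variables: list[str],
                      group_col: str = "individual_id",
                      priors: str = "proportional") -> ClassificationReport:
    """Leave-one-out classification.

    For each held-out row the group means, pooled covariance and priors are
    refit on the remaining rows (moment downdates, no full recompute); the
    variable set stays fixed — selection is *not* re-run per fold, matching
    the classical stepwise-DFA cross-validation procedure.
    """
    X, y, groups = _design(table, list(variables), group_col)
    n, p = X.shape
    g = len(groups)
    counts = np.bincount(y, minlength=g)
    if counts.min() < 2:
        raise DFAError("leave-one-out needs >= 2 rows per group")
    means = np.vstack([X[y == k].mean(axis=0) for k in range(g)])
    W = np.zeros((p, p))
    for k in range(g):
        d = X[y == k] - means[k]
        W += d.T @ d
    conf = np.zeros((g, g), int)
    for i in range(n):
        k = y[i]
        nk = counts[k]
        d = X[i] - means[k]
        W_i = W - (nk / (nk - 1.0)) * np.outer(d, d)
        mean_k = (nk * means[k] - X[i]) / (nk - 1.0)
        means_i = means.copy()
        means_i[k] = mean_k
        counts_i = counts.copy()
        counts_i[k] -= 1
        pooled = W_i / (n - 1 - g)
        pri = (counts_i / (n - 1.0) if priors == "proportional"
               else np.full(g, 1.0 / g))
        s = _fisher_scores(X[i:i + 1], means_i, pooled, pri)
        conf[k, int(np.argmax(s))] += 1
    return ClassificationReport(mode="loo", groups=groups, confusion=conf,
                                n=n)


# ---------------------------------------------------------------------------
# chance level and binomial tests
# ---------------------------------------------------------------------------

def chance_expectation(n_groups: int) -> float:
    """Group-size chance expectation, percent (100/g)."""
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    return 100.0 / n_groups


@dataclass
class BinomialTestResult:
    n_trials: int
    n_correct: int
    chance_p: float
    p_value: float
    method: str = "minlike"


def binomial_chance_test(n_correct: int, n_trials: int, chance_p: float,
                         method: str = "minlike") -> BinomialTestResult:
    """Exact two-tailed binomial test of a correct count against chance.

    ``minlike`` sums P(X=k) over all k at most as likely as the observed
    count (the SPSS/R convention); ``doubling`` doubles the smaller one-sided
    tail (capped at 1).
    """
    if not 0 <= n_correct <= n_trials:
        raise ValueError("need 0 <= n_correct <= n_trials")
    if not 0.0 < chance_p < 1.0:
        raise ValueError("chance_p must lie strictly inside (0, 1)")
    if method == "minlike":
        p = float(st.binomtest(n_correct, n_trials, chance_p,
                               alternative="two-sided").pvalue)
    elif method == "doubling":
        lo = st.binom.cdf(n_correct, n_trials, chance_p)
        hi = st.binom.sf(n_correct - 1, n_trials, chance_p)
        p = float(min(1.0, 2.0 * min(lo, hi)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return BinomialTestResult(n_trials=n_trials, n_correct=n_correct,
                              chance_p=chance_p, p_value=p, method=method)


# ---------------------------------------------------------------------------
# cross-valence orchestration
# ---------------------------------------------------------------------------

@dataclass
class CrossValenceResult:
    train_valence: str
    stepwise: StepwiseResult
    model: DFAModel
    reports: dict[str, ClassificationReport]
    binomials: dict[str, BinomialTestResult]
    scores: pd.DataFrame            # per-call first-two-function scores
    chance_percent: float = 0.0


def run_cross_valence_dfa(table: pd.DataFrame, train_valence: str,
                          f_enter: float = F_ENTER_DEFAULT,
                          f_remove: float = F_REMOVE_DEFAULT,
                          priors: str = "proportional",
                          chance_groups: int | None = None,
                          ) -> CrossValenceResult:
    """Train on one valence, test on the other.

    Runs stepwise selection and model fitting on the training-valence calls,
    reports resubstitution and leave-one-out accuracy there, transfers the
    model to the opposite valence, and attaches exact two-tailed binomial
    tests of each report's correct count against the group-size chance
    expectation.
    """
    if train_valence not in ("positive", "negative"):
        raise ValueError("train_valence must be 'positive' or 'negative'")
    test_valence = "negative" if train_valence == "positive" else "positive"
    train = table[table["valence"] == train_valence]
    test = table[table["valence"] == test_valence]
    if train.empty or test.empty:
        raise DFAError("both valences must be present in the table")
    for ind, sub in table.groupby("individual_id"):
        if set(sub["valence"]) != {"positive", "negative"}:
            raise DFAError(f"{ind} lacks calls in one valence")

    sw = stepwise_select(train, f_enter=f_enter, f_remove=f_remove)
    if not sw.selected:
        raise DFAError("stepwise selection chose no variables")
    model = fit_dfa(train, sw.selected, priors=priors)
    reports = {
        "resubstitution": classify(model, train, mode="resubstitution"),
        "loo": loo_crossvalidate(train, sw.selected, priors=priors),
        "transfer": classify(model, test, mode="transfer"),
    }
    g = chance_groups or len(model.groups)
    chance = chance_expectation(g) / 100.0
    binomials = {k: binomial_chance_test(r.n_correct, r.n, chance)
                 for k, r in reports.items()}
    sc = model.scores(table)
    scores = pd.DataFrame({
        "call_id": table["call_id"].to_numpy()
        if "call_id" in table.columns else np.arange(len(table)),
        "individual_id": table["individual_id"].to_numpy(),
        "valence": table["valence"].to_numpy(),
        "df1": sc[:, 0],
        "df2": sc[:, 1] if sc.shape[1] > 1 else np.zeros(len(table)),
    })
    return CrossValenceResult(train_valence=train_valence, stepwise=sw,
                              model=model, reports=reports,
                              binomials=binomials, scores=scores,
                              chance_percent=100.0 * chance)
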