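"""Median-split overall-survival screen: Kaplan-Meier curves, the two-group
log-rank test, and concordance between exosome abundance direction and
hazard direction.

For each marker gene the cohort is split at the median expression (ties go
to the low arm, making the split deterministic); the log-rank chi-square
(1 df) compares the arms, and the hazard direction is the sign of
observed - expected events in the high-expression arm (+1 when high
expression carries the higher hazard, i.e. worse survival).  Raw p-values
are reported (the screen mirrors a per-gene look-up; a Benjamini-Hochberg
column is available), with a "suggestive" tier for 0.05 <= p < 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

SIGNIFICANT_P = 0.05
SUGGESTIVE_P = 0.1


@dataclass
class KMCurve:
    """Product-limit survival curve."""

    times: np.ndarray  # distinct event times, increasing
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    censor_times: np.ndarray  # censoring marks

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        assert np.all((s >= -1e-12) & (s <= 1 + 1e-12)), "survival must lie in [0, 1]"
        assert np.all(np.diff(s) <= 1e-12), "survival must be non-increasing"

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def plot(self, ax=None, **kwargs):
        """Step plot of the curve (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.times])
        s = np.concatenate([[1.0], self.survival])
        ax.step(t, s, where="post", **kwargs)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        return ax


@dataclass
class LogRankResult:
    chi2: float
    p: float
    direction: int  # +1: high-expression arm has the higher hazard
    n_high: int
    n_low: int

    @property
    def tier(self) -> str:
        if self.p < SIGNIFICANT_P:
            return "significant"
        if self.p < SUGGESTIVE_P:
            return "suggestive"
        return "ns"


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    event_times = np.unique(t[e == 1])
    surv = []
    risk = []
    s = 1.0
    for et in event_times:
        n_at_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
        risk.append(n_at_risk)
    return KMCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(risk, dtype=int),
        censor_times=np.sort(t[e == 0]),
    )


def logrank_two_group(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float, float, float]:
    """Two-group log-rank test.

    Returns ``(chi2, p, observed_a, expected_a)`` where group *a* is the
    group whose observed/expected excess sets the direction sign.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a)
    eb = np.asarray(events_b)
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    in_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(all_t[all_e == 1])
    obs_a = exp_a = var = 0.0
    for et in event_times:
        at_risk = all_t >= et
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        dying = (all_t == et) & (all_e == 1)
        d = dying.sum()
        d_a = (dying & in_a).sum()
        obs_a += d_a
        exp_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0, float(obs_a), float(exp_a)
    stat = (obs_a - exp_a) ** 2 / var
    p = float(chi2.sf(stat, df=1))
    return float(stat), max(p, np.nextafter(0, 1)), float(obs_a), float(exp_a)


def logrank_median_split(cohort: pd.DataFrame, gene: str) -> LogRankResult:
    """Median-split log-rank test for one marker gene.

    ``cohort`` needs columns ``time_months``, ``event`` and
    ``expr_<gene>``.  Subjects at or below the median expression form the
    low arm (ties to low, deterministically); each arm must keep >= 2
    subjects.
    """
    col = f"expr_{gene}"
    if col not in cohort.columns:
        raise KeyError(f"cohort has no expression column {col!r}")
    expr = cohort[col].to_numpy(dtype=float)
    med = np.median(expr)
    high = expr > med
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high < 2 or n_low < 2:
        raise ValueError(
            f"degenerate median split for {gene!r}: {n_high} high / {n_low} low subjects"
        )
    t = cohort["time_months"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy()
    stat, p, obs, exp = logrank_two_group(t[high], e[high], t[~high], e[~high])
    direction = 0 if obs == exp else (1 if obs > exp else -1)
    return LogRankResult(chi2=stat, p=p, direction=direction, n_high=n_high, n_low=n_low)


def survival_screen(cohort: pd.DataFrame, genes: list[str]) -> pd.DataFrame:
    """Run the median-split log-rank screen over a list of genes."""
    rows = []
    for g in genes:
        try:
            r = logrank_median_split(cohort, g)
        except KeyError:
            warnings.warn(f"gene {g!r} missing from survival cohort; skipped", stacklevel=2)
            continue
        rows.append({"gene": g, "chi2": r.chi2, "p": r.p, "direction": r.direction, "tier": r.tier})
    return pd.DataFrame(rows, columns=["gene", "chi2", "p", "direction", "tier"]).set_index("gene")


def concordance_screen(
    metastatic_ratios: pd.DataFrame, survival_results: pd.DataFrame
) -> pd.DataFrame:
    """Concordance between exosome abundance direction and hazard direction.

    The abundance direction of a gene is the sign of the log of its most
    extreme metastatic/non-metastatic ratio.  A gene is *concordant* when
    abundance up in the metastatic lines coincides with the high-expression
    arm having worse survival (direction +1), or abundance down with
    direction -1.  Genes absent from either table are skipped with a warning.
    """
    rows = []
    for gene in survival_results.index:
        if gene not in metastatic_ratios.index:
            warnings.warn(f"gene {gene!r} missing from ratio table; skipped", stacklevel=2)
            continue
        logs = np.log(metastatic_ratios.loc[gene].to_numpy(dtype=float))
        extreme = logs[np.argmax(np.abs(logs))]
        abundance_dir = 0 if extreme == 0 else (1 if extreme > 0 else -1)
        direction = int(survival_results.loc[gene, "direction"])
        rows.append(
            {
                "gene": gene,
                "abundance_direction": abundance_dir,
                "hazard_direction": direction,
                "concordant": abundance_dir != 0 and abundance_dir == direction,
                "p": float(survival_results.loc[gene, "p"]),
                "significant": float(survival_results.loc[gene, "p"]) < SIGNIFICANT_P,
                "tier": survival_results.loc[gene, "tier"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "abundance_direction", "hazard_direction", "concordant", "p", "significant", "tier"],
    ).set_index("gene")
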