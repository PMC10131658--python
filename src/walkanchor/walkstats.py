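"""Cohort statistics for wrist-vs-ankle intensity misclassification.

The core question: within LONG walks — purposeful, continuous walking
established from the ankle — how often does the wrist-derived intensity
call the time sedentary?  Per participant this yields epoch counts per
class, misclassified sedentary minutes against a 20-minute clinically
important threshold, wrist AVM variability (CoV), and a Fisher exact test
of the observed sedentary/active split against the expectation that every
LONG-walk epoch is active, Bonferroni-corrected across participants.
Participants are then stratified into quartiles of percent-sedentary
(SED_Q1 lowest vs SED_Q4 highest) and compared with pooled-variance
two-sample t tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError


@dataclass(frozen=True)
class ParticipantWalkSummary:
    participant_id: str
    n_long_walks: int
    long_walk_minutes: float
    median_cadence_spm: float
    n_sedentary: int
    n_light: int
    n_mvpa: int
    pct_sedentary: float
    pct_light: float
    pct_mvpa: float
    sedentary_misclassified_min: float
    exceeds_clinical_threshold: bool
    avm_cov_pct: float
    fisher_p: float
    fisher_p_bonferroni: float = float("nan")


@dataclass(frozen=True)
class QuartileComparison:
    variable: str
    q1_mean: float
    q1_sd: float
    n1: int
    q4_mean: float
    q4_sd: float
    n2: int
    t: float
    df: int
    p: float


def intensity_distribution(
    n_sedentary: int, n_light: int, n_mvpa: int
) -> tuple[float, float, float]:
    """Class percentages of LONG-walk epochs (exact integer arithmetic in,
    percentages out)."""
    counts = (n_sedentary, n_light, n_mvpa)
    if any(c < 0 for c in counts):
        raise UsageError(f"negative epoch count in {counts}")
    total = sum(counts)
    if total == 0:
        raise UsageError("intensity distribution is undefined for zero epochs")
    return tuple(100.0 * c / total for c in counts)


def fisher_active_test(n_active: int, n_sedentary: int) -> float:
    """Two-sided Fisher exact p for observed active/sedentary epochs versus
    the all-active expectation.

    The 2x2 table contrasts the observed split with a pseudo-group of
    equal size in which every epoch is active::

        [[n_active,              n_sedentary],
         [n_active + n_sedentary, 0         ]]

    and the two-sided p sums hypergeometric probabilities of tables no
    more probable than the observed one.  With no sedentary epochs the
    observation equals the expectation and p = 1.
    """
    if n_active < 0 or n_sedentary < 0:
        raise UsageError("epoch counts must be non-negative")
    if n_active + n_sedentary == 0:
        raise UsageError("Fisher test undefined for zero epochs")
    table = [[n_active, n_sedentary], [n_active + n_sedentary, 0]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p -> min(1, p * m); m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise UsageError("p values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise UsageError(f"m={m} is smaller than the number of p values ({len(p)})")
    return np.minimum(1.0, p * m)


def clinical_threshold(
    n_sedentary_epochs: int, threshold_min: float = 20.0, epoch_length_s: float = 15.0
) -> tuple[float, bool]:
    """Sedentary-misclassified minutes and whether they reach the
    clinically important threshold (inclusive at exactly 20.0 min —
    roughly one day's worth of recommended MVPA lost over a week)."""
    if n_sedentary_epochs < 0:
        raise UsageError("epoch count must be non-negative")
    minutes = n_sedentary_epochs * epoch_length_s / 60.0
    return minutes, minutes >= threshold_min


def avm_cov(avm_mg) -> float:
    """Coefficient of variation (sample SD / mean x 100) of a participant's
    LONG-walk epoch AVMs."""
    x = np.asarray(avm_mg, dtype=float)
    if len(x) < 2:
        raise UsageError("AVM CoV requires at least 2 epochs")
    mean = x.mean()
    if mean <= 0:
        raise UsageError("AVM CoV undefined for non-positive mean")
    return float(x.std(ddof=1) / mean * 100.0)


def quartile_groups(
    pct_sedentary: dict[str, float],
) -> tuple[list[str], list[str]]:
    """Bottom (SED_Q1) and top (SED_Q4) quartile membership by percent of
    LONG-walk epochs classified sedentary.

    Group size is ceil(n/4) (35 participants -> groups of 9).  Sorting is
    by (value, participant id) so ties at a quartile boundary resolve
    deterministically.
    """
    n = len(pct_sedentary)
    if n < 4:
        raise UsageError(f"quartile stratification needs >= 4 participants, got {n}")
    k = int(np.ceil(n / 4))
    ordered = sorted(pct_sedentary, key=lambda pid: (pct_sedentary[pid], pid))
    return ordered[:k], ordered[-k:]


def pooled_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample Student t from summary statistics.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.  Zero pooled
    variance yields t = 0 for equal means and signed infinity otherwise.
    """
    if n1 < 2 or n2 < 2:
        raise UsageError("pooled t requires n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise UsageError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    diff = mean1 - mean2
    if sp2 == 0:
        t = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    else:
        t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return float(t), df, p


# ---------------------------------------------------------------------------
# cohort assembly


def summarize_participant(
    participant_id: str,
    walk_epochs,
    long_walks,
) -> ParticipantWalkSummary:
    """Fold one participant's labelled LONG-walk epochs into a summary row
    (Bonferroni field filled in at cohort level)."""
    labels = [e.label for e in walk_epochs]
    n_sed = labels.count("sedentary")
    n_light = labels.count("light")
    n_mvpa = labels.count("MVPA")
    total = n_sed + n_light + n_mvpa
    if total == 0:
        raise UsageError(f"participant {participant_id} has no LONG-walk epochs")
    pct = intensity_distribution(n_sed, n_light, n_mvpa)
    minutes, exceeds = clinical_threshold(n_sed)
    longs = [b for b in long_walks if b.is_long]
    cadences = [b.median_cadence_spm for b in longs]
    avms = [e.avm_mg for e in walk_epochs]
    return ParticipantWalkSummary(
        participant_id=participant_id,
        n_long_walks=len(longs),
        long_walk_minutes=sum(b.duration_s for b in longs) / 60.0,
        median_cadence_spm=float(np.median(cadences)) if cadences else float("nan"),
        n_sedentary=n_sed,
        n_light=n_light,
        n_mvpa=n_mvpa,
        pct_sedentary=pct[0],
        pct_light=pct[1],
        pct_mvpa=pct[2],
        sedentary_misclassified_min=minutes,
        exceeds_clinical_threshold=exceeds,
        avm_cov_pct=avm_cov(avms) if len(avms) >= 2 and np.mean(avms) > 0 else float("nan"),
        fisher_p=fisher_active_test(n_light + n_mvpa, n_sed),
    )


_COMPARED_VARIABLES = {
    "n_long_walks": "n_long_walks",
    "long_walk_minutes": "long_walk_minutes",
    "median_cadence_spm": "median_cadence_spm",
    "pct_sedentary": "pct_sedentary",
    "avm_cov_pct": "avm_cov_pct",
}


def cohort_report(
    summaries: list[ParticipantWalkSummary],
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the cohort tables: per-participant summaries with
    Bonferroni-adjusted Fisher p values, and SED_Q1-vs-SED_Q4 pooled t
    comparisons of walking behavior.  Writes both as CSV when ``out_dir``
    is given."""
    if not summaries:
        raise UsageError("cohort_report requires at least one participant")
    m = len(summaries)
    adjusted = bonferroni([s.fisher_p for s in summaries], m)
    rows = []
    for s, p_adj in zip(summaries, adjusted):
        d = s.__dict__.copy()
        d["fisher_p_bonferroni"] = float(p_adj)
        rows.append(d)
    table = pd.DataFrame(rows)
    n_exceed = int(table["exceeds_clinical_threshold"].sum())
    table.attrs["n_exceeding_clinical_threshold"] = n_exceed
    table.attrs["pct_exceeding_clinical_threshold"] = 100.0 * n_exceed / m

    comparisons = pd.DataFrame()
    if m >= 4:
        q1, q4 = quartile_groups(
            {s.participant_id: s.pct_sedentary for s in summaries}
        )
        assert not set(q1) & set(q4), "quartile groups must be disjoint"
        sub = table.set_index("participant_id")
        comp_rows = []
        for label, col in _COMPARED_VARIABLES.items():
            g1 = sub.loc[q1, col].dropna()
            g4 = sub.loc[q4, col].dropna()
            if len(g1) < 2 or len(g4) < 2:
                continue
            t, df, p = pooled_t(
                g1.mean(), g1.std(ddof=1), len(g1), g4.mean(), g4.std(ddof=1), len(g4)
            )
            comp_rows.append(
                QuartileComparison(
                    variable=label,
                    q1_mean=float(g1.mean()), q1_sd=float(g1.std(ddof=1)), n1=len(g1),
                    q4_mean=float(g4.mean()), q4_sd=float(g4.std(ddof=1)), n2=len(g4),
                    t=t, df=df, p=p,
                ).__dict__
            )
        comparisons = pd.DataFrame(comp_rows)
        comparisons.attrs["sed_q1"] = q1
        comparisons.attrs["sed_q4"] = q4

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "participant_summary.csv", index=False)
        comparisons.to_csv(out_dir / "quartile_comparisons.csv", index=False)
    return table, comparisons
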