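"""Simulation-study harness: knot selection by three rules over replicate
datasets, selection-frequency tables, and exact pairwise accuracy tests.

For each replicate dataset the chosen number of knots is recorded under the
parametric-bootstrap 2-df forward procedure and under AIC and BIC
minimization, then tabulated over K = 0..Kmax.  Accuracy (correct-at-2
counts under the two-knot true model) is compared between methods with a
two-sided Fisher's exact test on the 2x2 correct/incorrect table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import fisher_exact

from .fitting import FitError
from .selection import SelectionConfig, select_by_ic, select_knots_forward
from .simulate import SimConfig, TrueModel, simulate_dataset

__all__ = [
    "StudyResult",
    "run_simulation_study",
    "fisher_exact_2x2",
    "study_report",
    "frequency_plot",
]

METHODS = ("bootstrap", "AIC", "BIC")


@dataclass
class StudyResult:
    """Selection frequencies per method for one simulation condition."""

    condition: dict
    frequencies: pd.DataFrame  # index: method, columns: K = 0..Kmax
    correct_at: dict           # method -> count at the true K
    fisher_p: dict             # pair label -> two-sided exact p
    n_replicates: int
    n_failed: int
    true_K: int
    chosen: pd.DataFrame | None = None  # per-replicate chosen K by method


def fisher_exact_2x2(correct_a: int, total_a: int, correct_b: int,
                     total_b: int) -> float:
    """Two-sided Fisher's exact p for correct/incorrect counts of two methods.

    Uses the point-probability rule (sum of tables no more probable than the
    observed one), the convention of standard exact-test software.
    """
    for c, t in ((correct_a, total_a), (correct_b, total_b)):
        if not 0 <= c <= t:
            raise ValueError("counts must satisfy 0 <= correct <= total")
    table = [[correct_a, total_a - correct_a], [correct_b, total_b - correct_b]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def _one_replicate(seed_seq, sim: SimConfig, sel: SelectionConfig,
                   model: TrueModel, x):
    rng = np.random.default_rng(seed_seq.spawn(1)[0])
    data, _ = simulate_dataset(sim, rng, model=model, x=x)
    out = {}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = select_knots_forward(data, sel, rng=seed_seq)
            out["bootstrap"] = res.chosen_K
            out["AIC"] = select_by_ic(data, "AIC", sel.Kmax, sel.fit)
            out["BIC"] = select_by_ic(data, "BIC", sel.Kmax, sel.fit)
    except FitError as err:
        return {"error": str(err)}
    return out


def run_simulation_study(sim: SimConfig, sel: SelectionConfig | None = None,
                         model: TrueModel | None = None,
                         x: np.ndarray | None = None,
                         seed: int | None = None,
                         n_jobs: int = 1) -> StudyResult:
    """Run one condition of the knot-selection study.

    Replicates are independent, each driven by its own spawned seed, so
    results are invariant to execution order and may run in parallel.  The
    study aborts if more than 10% of replicates fail.
    """
    sel = sel or SelectionConfig()
    model = model or TrueModel()
    master = np.random.SeedSequence(seed if seed is not None else sim.seed)
    children = master.spawn(sim.replicates)
    rows = Parallel(n_jobs=n_jobs)(
        delayed(_one_replicate)(c, sim, sel, model, x) for c in children)
    failed = [r for r in rows if "error" in r]
    good = [r for r in rows if "error" not in r]
    if len(failed) > 0.1 * sim.replicates:
        raise FitError(
            f"{len(failed)}/{sim.replicates} replicates failed: "
            f"{failed[0]['error']}")
    chosen = pd.DataFrame(good)
    Ks = list(range(sel.Kmax + 1))
    freq = pd.DataFrame(0, index=list(METHODS), columns=Ks)
    for m in METHODS:
        counts = chosen[m].value_counts()
        for K, c in counts.items():
            freq.loc[m, int(K)] = int(c)
    true_K = len(model.knots)
    correct = {m: int(freq.loc[m, true_K]) if true_K in freq.columns else 0
               for m in METHODS}
    n_rep = len(good)
    fisher_p = {
        "bootstrap_vs_AIC": fisher_exact_2x2(
            correct["bootstrap"], n_rep, correct["AIC"], n_rep),
        "bootstrap_vs_BIC": fisher_exact_2x2(
            correct["bootstrap"], n_rep, correct["BIC"], n_rep),
    }
    condition = {"n": sim.n, "p0": sim.p0, "weighted": sim.weighted,
                 "alpha": sel.alpha, "D1": sel.D1, "Kmax": sel.Kmax}
    return StudyResult(condition=condition, frequencies=freq,
                       correct_at=correct, fisher_p=fisher_p,
                       n_replicates=n_rep, n_failed=len(failed),
                       true_K=true_K, chosen=chosen)


def study_report(result: StudyResult) -> str:
    """Plain-text accuracy report for one study condition."""
    c = result.condition
    lines = [
        f"Condition: n={c['n']}, p0={c['p0']}, weighted={c['weighted']}, "
        f"alpha={c['alpha']}, D1={c['D1']}",
        f"Replicates: {result.n_replicates} (failed: {result.n_failed})",
        "",
        "Selection frequencies (rows: method, columns: chosen K):",
        result.frequencies.to_string(),
        "",
        f"Correct at K={result.true_K}: " + ", ".join(
            f"{m}={result.correct_at[m]}" for m in METHODS),
        "Fisher exact (two-sided): " + ", ".join(
            f"{k}: p={v:.3f}" for k, v in result.fisher_p.items()),
    ]
    return "\n".join(lines)


def frequency_plot(result: StudyResult, path: str) -> None:
    """Frequency-polygon plot of chosen K per method, saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"bootstrap": "red", "AIC": "black", "BIC": "blue"}
    for m in METHODS:
        ax.plot(result.frequencies.columns, result.frequencies.loc[m],
                marker="o", color=colors[m], label=m)
    ax.axvline(result.true_K, ls=":", color="gray")
    ax.set_xlabel("chosen number of knots K")
    ax.set_ylabel(f"frequency (of {result.n_replicates})")
    c = result.condition
    ax.set_title(f"n={c['n']}, p0={c['p0']}, weighted={c['weighted']}, "
                 f"alpha={c['alpha']}", fontsize=9)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
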