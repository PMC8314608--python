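import numpy as np
import pandas as pd
import pytest

from targetfunnel import CompendiumSpec, ExpressionMatrix, generate_expression_compendium


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """10 genes, 4 tumors, two normal tissues of unequal size (3 + 5)."""
    spec = CompendiumSpec(
        n_genes=10, n_tumor=4,
        tissues=(("liver", 3), ("brain", 5)),
        baseline_mean=6.0, baseline_sd=1.0,
        planted_overexpressed=(("HOT1", 3.0),), seed=7)
    return generate_expression_compendium(spec)


@pytest.fixture
def hand_matrix() -> ExpressionMatrix:
    """2-gene fixture with hand-checkable means."""
    values = pd.DataFrame(
        {"t1": [8.0, 5.0], "t2": [8.0, 5.0], "n1": [6.0, 5.0], "n2": [6.0, 5.0]},
        index=pd.Index(["gA", "gB"], name="gene_id"))
    classes = pd.Series({"t1": "tumor", "t2": "tumor", "n1": "normal", "n2": "normal"})
    tissue = pd.Series({"t1": "tumor", "t2": "tumor", "n1": "liver", "n2": "brain"})
    return ExpressionMatrix(values, classes, tissue)


def brute_force_logrank(times, events, in_g1):
    """Independent per-event-time O/E/V tabulation by exhaustive loop."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    in_g1 = np.asarray(in_g1, bool)
    O1 = E1 = V = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in_g1).sum()
        d = ((times == t) & events).sum()
        d1 = ((times == t) & events & in_g1).sum()
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = (O1 - E1) ** 2 / V if V > 0 else 0.0
    return O1, E1, V, stat
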