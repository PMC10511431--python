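import numpy as np
import pandas as pd
import pytest

from pancontext.synthetic import (
    ModuleSpec,
    SyntheticSpec,
    generate_cell_line_panel,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """A fast three-type cohort with one module of each flavor."""
    return SyntheticSpec(
        cancer_types=[("ALPHA", 80), ("BRAVO", 80), ("CHARLIE", 80)],
        n_genes=150,
        planted_modules=[
            ModuleSpec("POSMOD", 20, rho=0.7),
            ModuleSpec("NEGMOD", 15, rho=-0.6),
            ModuleSpec("SWITCHMOD", 15, rho_wt=-0.4, rho_mut=0.4),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    return generate_cell_line_panel(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def brute_force_spearman(x, y) -> float:
    """Independent oracle: mid-ranks by sorting, then the Pearson formula."""

    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j < len(v) and v[order[j]] == v[order[i]]:
                j += 1
            avg = (i + j + 1) / 2.0  # average of 1-based positions i+1..j
            for k in range(i, j):
                ranks[order[k]] = avg
            i = j
        return ranks

    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def brute_force_bh(pvals):
    """Textbook step-up BH q-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
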