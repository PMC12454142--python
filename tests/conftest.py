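import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lifecost as lc

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_world() -> lc.SyntheticWorld:
    """A compact world exercising every commodity group and trade."""
    cfg = lc.WorldConfig(
        grid_rows=16, grid_cols=16, n_countries=4, n_commodities=10,
        n_animal_commodities=3, n_species=60, seed=11,
    )
    return lc.generate_world(cfg)


@pytest.fixture(scope="session")
def small_result(small_world) -> lc.PipelineResult:
    return lc.compute_all(small_world)


@pytest.fixture(scope="session")
def autarky_world() -> lc.SyntheticWorld:
    cfg = lc.WorldConfig(
        grid_rows=12, grid_cols=12, n_countries=3, n_commodities=8,
        n_animal_commodities=2, n_species=40, seed=5, trade_mode="autarky",
    )
    return lc.generate_world(cfg)


def expansion_quantile(values, weights, q: float) -> float:
    """Oracle: expand each value `weight` times, take the plain type-1 quantile."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=int)
    expanded = np.repeat(v, w)
    return float(np.quantile(expanded, q, method="inverted_cdf"))


def iterative_provenance(production: pd.Series, trade: pd.DataFrame,
                         tol: float = 1e-14, max_iter: int = 10000) -> pd.DataFrame:
    """Oracle: propagate origin mixes through the trade graph to a fixed point."""
    countries = list(production.index)
    p = production.to_numpy(dtype=float)
    t = trade.to_numpy(dtype=float)
    supply = p + t.sum(axis=0)
    keep = supply > 0
    idx = np.flatnonzero(keep)
    f = np.zeros((len(idx), len(idx)))
    p_k = p[idx]
    s_k = supply[idx]
    t_k = t[np.ix_(idx, idx)]
    for _ in range(max_iter):
        new = np.diag(p_k / s_k) + (t_k.T / s_k[:, None]) @ f
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    kept = [countries[i] for i in idx]
    return pd.DataFrame(f, index=kept, columns=kept)


def random_balanced_network(rng: np.random.Generator, n: int):
    """A random trade network with exports drawn from production (never exceeding supply)."""
    countries = [f"C{i:02d}" for i in range(n)]
    p = pd.Series(rng.uniform(1.0, 100.0, size=n), index=countries)
    if n > 1 and rng.random() < 0.3:
        p.iloc[rng.integers(n)] = 0.0  # occasional pure re-exporter
    t = np.zeros((n, n))
    for i in range(n):
        frac = 0.6 * rng.random()
        partners = rng.permutation([j for j in range(n) if j != i])[: rng.integers(0, n)]
        for j in partners:
            t[i, j] = p.iloc[i] * frac / max(1, len(partners))
    trade = pd.DataFrame(t, index=countries, columns=countries)
    # give zero-production countries something to re-export
    supply = p.values + t.sum(axis=0)
    for i in range(n):
        if supply[i] > 0:
            out = trade.values[i].sum()
            if out > supply[i]:
                trade.values[i] *= 0.9 * supply[i] / out
        else:
            trade.values[i] = 0.0
    return p, trade
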