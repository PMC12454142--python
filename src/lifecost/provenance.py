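"""Trade re-export correction and consumption-basis impacts.

Apparent imports do not reveal where a commodity was actually grown: much
trade is re-exported through intermediaries. Following the standard
re-export-correction accounting, each country's supply of a commodity is a
mix of its own primary production and the supply mixes of the countries it
imports from:

    F[i, .] = (P_i / s_i) · e_i + Σ_j (T[j→i] / s_i) · F[j, .]
    s_i = P_i + Σ_j T[j→i]

Every country's exports carry its supply's origin mix, so the fixed point F
(solved here as one dense linear system) gives the provenance portfolio of
each country's domestic use. Consumption-basis per-kg impacts are then the
provenance-share-weighted averages of the origin countries' production-basis
impacts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .spatial import ImpactValue


class ProvenanceError(ValueError):
    """The provenance system is unsolvable (e.g. pure re-export cycle)."""


def primary_equivalent_flows(
    flows: dict[str, pd.DataFrame],
    conversion: pd.DataFrame,
    processed: set[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Convert processed-commodity flows to primary equivalents.

    ``conversion`` has columns (processed, primary, extraction_rate); a flow
    of X tonnes of a processed commodity becomes X / extraction_rate tonnes
    of its primary (flour at extraction 0.8 counts as 1.25× its mass in
    wheat), accumulated onto the primary commodity's matrix. ``processed``
    names the flows that must be converted (default: those with a conversion
    row); a processed commodity without a conversion row is an error. All
    other flows are primary and pass through unchanged.
    """
    conv = {r.processed: (r.primary, float(r.extraction_rate))
            for r in conversion.itertuples()}
    for name, (_, rate) in conv.items():
        if rate <= 0:
            raise ValueError(f"extraction rate for {name!r} must be > 0")
    if processed is None:
        processed = set(conv)
    unmapped = sorted(set(processed) - set(conv))
    if unmapped:
        raise KeyError(f"processed commodities without a primary mapping: {unmapped}")
    out: dict[str, pd.DataFrame] = {}
    for name, t in flows.items():
        if name in processed:
            primary, rate = conv[name]
            add = t / rate
        else:
            primary, add = name, t.copy()
        out[primary] = out[primary].add(add, fill_value=0.0) if primary in out else add
    return out


def provenance_shares(production: pd.Series, trade: pd.DataFrame) -> pd.DataFrame:
    """Solve the re-export fixed point for one commodity.

    Parameters
    ----------
    production:
        Primary production P by country (tonnes/yr).
    trade:
        Bilateral flows, origin × destination (tonnes/yr), zero diagonal.

    Returns
    -------
    DataFrame
        Rows: consumer countries with positive supply; columns: origin
        countries; each row sums to 1 and gives the origin mix of that
        country's domestic use. Countries with zero supply are dropped with
        a warning.
    """
    countries = list(production.index)
    p = production.reindex(countries).to_numpy(dtype=float)
    t = trade.reindex(index=countries, columns=countries).fillna(0.0).to_numpy(dtype=float)
    if (p < 0).any() or (t < 0).any():
        raise ValueError("production and trade flows must be non-negative")
    supply = p + t.sum(axis=0)
    keep = supply > 0
    dropped = [c for c, k in zip(countries, keep) if not k]
    if dropped:
        warnings.warn(f"countries with zero supply dropped from provenance: {dropped}")
    sub = np.ix_(keep, keep)
    p_k, t_k, s_k = p[keep], t[sub], supply[keep]
    # (I - M) F = diag(P/s), with M[i, j] = T[j -> i] / s_i
    m = t_k.T / s_k[:, None]
    a = np.eye(len(s_k)) - m
    b = np.diag(p_k / s_k)
    try:
        f = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise ProvenanceError(
            "provenance system is singular (pure re-export cycle with no production?)"
        ) from exc
    if not np.all(np.isfinite(f)):
        raise ProvenanceError("provenance solve produced non-finite shares")
    rows = f.sum(axis=1)
    if np.abs(rows - 1.0).max() > 1e-6:
        raise ProvenanceError("provenance rows do not sum to 1; inconsistent trade data")
    kept = [c for c, k in zip(countries, keep) if k]
    return pd.DataFrame(np.clip(f, 0.0, None), index=kept, columns=kept)


def consumption_perkg_impact(
    commodity: str,
    country: str,
    shares: pd.Series,
    production_impacts: dict[str, ImpactValue],
) -> ImpactValue:
    """Provenance-weighted per-kg impact of consuming a commodity.

    ``shares`` maps origin country → share of the consumer's domestic use;
    every origin with a positive share must have a production-basis impact.
    """
    value = 0.0
    components = {"crop": 0.0, "grazing": 0.0, "feed": 0.0}
    origin_shares: dict[str, float] = {}
    origin_values: dict[str, float] = {}
    for origin, share in shares.items():
        if share <= 0:
            continue
        if origin not in production_impacts or production_impacts[origin] is None:
            raise ProvenanceError(
                f"{commodity}: origin {origin!r} has share {share:.3g} for consumer "
                f"{country!r} but no production impact value"
            )
        v = production_impacts[origin]
        value += share * v.value
        for k in components:
            components[k] += share * v.components.get(k, 0.0)
        origin_shares[str(origin)] = float(share)
        origin_values[str(origin)] = float(v.value)
    return ImpactValue(
        value=value, commodity=commodity, country=country, basis="consumption",
        components=components, origin_shares=origin_shares, origin_values=origin_values,
    )
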