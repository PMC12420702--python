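"""Convariety contrasts, multiple-testing correction and trait correlations.

Contrasts are run on accession BLUEs with the one-way model y = mu + v + e:
pairwise group-mean differences are tested with pooled-variance t statistics
(the single-residual-variance model; Welch optional), the family of pairwise
p values is adjusted with Holm's step-down procedure, and the outcome is
summarised as a compact letter display in which two groups share a letter
exactly when they are not significantly different.

Trait-trait relationships are pairwise-complete correlations between BLUE
vectors (Pearson by default, Spearman optional), again Holm-adjusted across
all trait pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastTable",
    "CorrelationMatrix",
    "holm_adjust",
    "compact_letter_display",
    "convariety_contrasts",
    "trait_correlations",
]


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p values, in the input order.

    Sort ascending; adjusted_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


def compact_letter_display(
    significant: np.ndarray, groups: Sequence[str]
) -> Dict[str, str]:
    """Letters such that two groups share a letter iff not significantly different.

    Insert-and-absorb: start from one set holding every group; for each
    significant pair split every set containing both; discard sets absorbed
    by (subsets of) another.  Deterministic for a given group order.
    """
    sig = np.asarray(significant, dtype=bool)
    k = len(groups)
    if sig.shape != (k, k):
        raise ValueError("significance matrix shape does not match groups")
    if not np.array_equal(sig, sig.T) or sig.diagonal().any():
        raise ValueError("significance matrix must be symmetric with false diagonal")
    sets: List[set] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not sig[i, j]:
            continue
        new_sets: List[set] = []
        for s in sets:
            if i in s and j in s:
                new_sets.append(s - {i})
                new_sets.append(s - {j})
            else:
                new_sets.append(s)
        # absorb: drop empty sets, duplicates and sets contained in another
        absorbed: List[set] = []
        for a, s in enumerate(new_sets):
            if not s:
                continue
            dominated = any(
                (s < o) or (s == o and b < a)
                for b, o in enumerate(new_sets)
                if b != a
            )
            if not dominated:
                absorbed.append(s)
        sets = absorbed
    # stable letter order: by smallest member index
    sets.sort(key=lambda s: sorted(s))
    letters = {g: "" for g in groups}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter_idx, s in enumerate(sets):
        ch = alphabet[letter_idx % len(alphabet)]
        if letter_idx >= len(alphabet):
            ch = ch * (letter_idx // len(alphabet) + 1)
        for gi in sorted(s):
            letters[groups[gi]] += ch
    return letters


@dataclass
class ContrastTable:
    """Group means, pairwise tests and letter display for one trait."""

    group_stats: pd.DataFrame  # index group; columns n, mean, se
    pairwise: pd.DataFrame     # columns a, b, diff, t, df, p_raw, p_holm, significant
    letters: Dict[str, str]
    alpha: float
    excluded: List[str] = field(default_factory=list)


def convariety_contrasts(
    blues: Mapping[str, float] | pd.Series,
    convariety: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    welch: bool = False,
) -> ContrastTable:
    """Pairwise convariety differences on accession BLUEs with Holm control.

    Groups with fewer than two accessions are excluded from testing and
    listed in ``excluded``.
    """
    blues = pd.Series(blues, dtype=float)
    conv = pd.Series(convariety).reindex(blues.index)
    df = pd.DataFrame({"value": blues, "group": conv}).dropna()
    sizes = df.groupby("group").size()
    excluded = sorted(sizes.index[sizes < 2])
    df = df[~df["group"].isin(excluded)]
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two convarieties with >= 2 accessions")

    stats_df = df.groupby("group")["value"].agg(n="size", mean="mean", var="var")
    # pooled residual variance of the one-way model
    ss_within = float(((stats_df["n"] - 1) * stats_df["var"]).sum())
    df_resid = int(stats_df["n"].sum() - len(groups))
    s2p = ss_within / df_resid if df_resid > 0 else np.nan
    stats_df["se"] = np.sqrt(s2p / stats_df["n"])

    rows = []
    for a, b in itertools.combinations(groups, 2):
        na, nb = stats_df.loc[a, "n"], stats_df.loc[b, "n"]
        diff = stats_df.loc[a, "mean"] - stats_df.loc[b, "mean"]
        if welch:
            va, vb = stats_df.loc[a, "var"] / na, stats_df.loc[b, "var"] / nb
            se = np.sqrt(va + vb)
            dof = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
        else:
            se = np.sqrt(s2p * (1.0 / na + 1.0 / nb))
            dof = df_resid
        if se == 0:
            t = 0.0 if diff == 0 else np.sign(diff) * np.inf
        else:
            t = diff / se
        p = float(2 * stats.t.sf(abs(t), dof)) if np.isfinite(t) else 0.0
        rows.append({"a": a, "b": b, "diff": diff, "t": t, "df": dof, "p_raw": p})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_adjust(pairwise["p_raw"].to_numpy())
    pairwise["significant"] = pairwise["p_holm"] < alpha

    k = len(groups)
    sig = np.zeros((k, k), dtype=bool)
    gi = {g: i for i, g in enumerate(groups)}
    for _, r in pairwise.iterrows():
        sig[gi[r["a"]], gi[r["b"]]] = sig[gi[r["b"]], gi[r["a"]]] = bool(r["significant"])
    letters = compact_letter_display(sig, groups)
    return ContrastTable(
        group_stats=stats_df[["n", "mean", "se"]],
        pairwise=pairwise,
        letters=letters,
        alpha=alpha,
        excluded=list(excluded),
    )


@dataclass
class CorrelationMatrix:
    """Pairwise-complete trait correlations on BLUEs."""

    r: pd.DataFrame
    n: pd.DataFrame
    p_raw: pd.DataFrame
    p_holm: pd.DataFrame
    method: str
    untested: List[Tuple[str, str]] = field(default_factory=list)


def trait_correlations(
    blue_tables: Mapping[str, pd.Series],
    method: str = "pearson",
    alpha: float = 0.05,
    min_n: int = 3,
) -> CorrelationMatrix:
    """Correlations between trait BLUE vectors over shared accessions.

    Each trait pair uses its complete cases; pairs with fewer than ``min_n``
    shared accessions are left untested (NaN).  P values come from the exact
    t transform of r and are Holm-adjusted over all tested pairs.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be pearson or spearman")
    traits = list(blue_tables)
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    n = pd.DataFrame(0, index=traits, columns=traits)
    p = pd.DataFrame(np.nan, index=traits, columns=traits)
    untested: List[Tuple[str, str]] = []
    tested_pairs, raw_ps = [], []
    for a, b in itertools.combinations(traits, 2):
        sa, sb = pd.Series(blue_tables[a]), pd.Series(blue_tables[b])
        common = sa.index.intersection(sb.index)
        xa, xb = sa[common].astype(float), sb[common].astype(float)
        mask = xa.notna() & xb.notna()
        m = int(mask.sum())
        n.loc[a, b] = n.loc[b, a] = m
        if m < min_n:
            untested.append((a, b))
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        if method == "pearson":
            rv, pv = stats.pearsonr(xa[mask], xb[mask])
        else:
            rv, pv = stats.spearmanr(xa[mask], xb[mask])
        r.loc[a, b] = r.loc[b, a] = rv
        p.loc[a, b] = p.loc[b, a] = pv
        tested_pairs.append((a, b))
        raw_ps.append(pv)
    p_holm = pd.DataFrame(np.nan, index=traits, columns=traits)
    if raw_ps:
        adj = holm_adjust(raw_ps)
        for (a, b), v in zip(tested_pairs, adj):
            p_holm.loc[a, b] = p_holm.loc[b, a] = v
    for t in traits:
        n.loc[t, t] = int(pd.Series(blue_tables[t]).notna().sum())
    return CorrelationMatrix(
        r=r, n=n, p_raw=p, p_holm=p_holm, method=method, untested=untested
    )
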