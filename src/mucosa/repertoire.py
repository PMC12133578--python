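"""TCR repertoire statistics: overlap, segment-usage enrichment, clonal
expansion structure, CDR3 composition, motifs and inter-sample sharing."""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact, norm
from statsmodels.stats.multitest import multipletests

from .datamodel import AA_ALPHABET

log = logging.getLogger("mucosa")

KEY_MODES = ("nt", "aa", "v+aa")


def _key_columns(key_mode: str) -> list[str]:
    if key_mode == "nt":
        return ["v_call", "cdr3_nt"]     # default clonotype definition
    if key_mode == "aa":
        return ["cdr3_aa"]
    if key_mode == "v+aa":
        return ["v_call", "cdr3_aa"]
    raise ValueError(f"unknown key mode {key_mode!r}")


@dataclass
class ClonotypeVector:
    """Clonotype key -> template count, with the totals used by overlap stats."""

    counts: dict[tuple, int]
    key_mode: str

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty clonotype vector")
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("clonotype counts must be positive")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)


def aggregate(table: pd.DataFrame, key_mode: str = "nt",
              by: str = "sample_id") -> dict[str, ClonotypeVector]:
    """Aggregate a clonotype table into per-group count vectors.

    Counts are summed over duplicate keys (``key_mode='aa'`` merges
    nucleotide synonyms). Total template counts are conserved.
    """
    if table.empty:
        raise ValueError("empty clonotype table")
    cols = _key_columns(key_mode)
    out: dict[str, ClonotypeVector] = {}
    for group, grp in table.groupby(by, sort=True):
        agg = grp.groupby(cols, sort=True)["count"].sum()
        counts = {k if isinstance(k, tuple) else (k,): int(v)
                  for k, v in agg.items()}
        out[group] = ClonotypeVector(counts=counts, key_mode=key_mode)
    return out


def morisita_horn(a: ClonotypeVector, b: ClonotypeVector) -> float:
    """Morisita-Horn similarity: 2 Σ x_i y_i / [(Σx_i²/X² + Σy_i²/Y²) X Y].

    1 for identical compositions, 0 for disjoint repertoires.
    """
    X, Y = a.total, b.total
    keys = set(a.counts) | set(b.counts)
    xy = sum(a.counts.get(k, 0) * b.counts.get(k, 0) for k in keys)
    sx2 = sum(v * v for v in a.counts.values())
    sy2 = sum(v * v for v in b.counts.values())
    # algebraically (sx2/X^2 + sy2/Y^2) * X * Y, arranged so the identity
    # case evaluates to exactly 1.0 in floating point
    return 2.0 * xy / (sx2 * (Y / X) + sy2 * (X / Y))


def overlap_matrix(vectors: Mapping[str, ClonotypeVector]) -> pd.DataFrame:
    names = sorted(vectors)
    M = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, j in combinations(names, 2):
        M.loc[i, j] = M.loc[j, i] = morisita_horn(vectors[i], vectors[j])
    return M


# ---------------------------------------------------------------------------
# V-segment usage

def _segment_sample_counts(table: pd.DataFrame, count_mode: str) -> pd.DataFrame:
    """sample x segment matrix of unique-clonotype (or template) counts."""
    cols = _key_columns("nt")
    uniq = table.groupby(["sample_id"] + cols, sort=True, dropna=False)["count"] \
                .sum().reset_index()
    if count_mode == "unique":
        uniq["count"] = 1
    elif count_mode != "templates":
        raise ValueError(f"unknown count mode {count_mode!r}")
    return uniq.pivot_table(index="sample_id", columns="v_call", values="count",
                            aggfunc="sum", fill_value=0)


def _mom_dispersion(y: np.ndarray, mu: np.ndarray, floor: float = 1e-8) -> float:
    """Method-of-moments NB alpha (var = mu + alpha mu²), floored."""
    num = float(np.sum((y - mu) ** 2 - mu))
    den = float(np.sum(mu ** 2))
    if den <= 0:
        return floor
    return max(floor, num / den)


def v_usage_test(table: pd.DataFrame, groups: tuple[str, str] = ("ACD", "HC"),
                 group_by: str = "condition", count_mode: str = "unique",
                 high_frequency_threshold: float = 0.01) -> pd.DataFrame:
    """Per-segment negative-binomial test of usage between two groups.

    For each V segment, per-sample segment counts are modeled by a NB
    regression on the group indicator with offset log(sample total); the
    dispersion is estimated per segment by pooled method-of-moments (floor
    1e-8) and the group effect tested by a two-sided Wald test, with BH
    across segments. ``lfc`` is the log2 fold change (first group over
    second). Segments absent everywhere are dropped and reported. The
    ``frequency_class`` marks segments used by more than
    ``high_frequency_threshold`` of pooled clones.
    """
    ga, gb = groups
    sample_group = table.groupby("sample_id")[group_by].first()
    counts = _segment_sample_counts(table, count_mode)
    grp = sample_group.reindex(counts.index)
    keep = grp.isin([ga, gb])
    counts, grp = counts.loc[keep], grp.loc[keep]
    for g in (ga, gb):
        if (grp == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    offset = np.log(totals)
    x = (grp == ga).to_numpy(dtype=float)
    X = sm.add_constant(x)
    pooled_fraction = counts.sum(axis=0) / counts.to_numpy().sum()

    dropped = [v for v in counts.columns if counts[v].sum() == 0]
    if dropped:
        log.warning("segments absent everywhere dropped: %s", dropped)
    rows = []
    for v in counts.columns:
        y = counts[v].to_numpy(dtype=float)
        if y.sum() == 0:
            continue
        # group-pooled rate estimates for the moment estimator
        mu = np.empty_like(y)
        for g in (ga, gb):
            m = (grp == g).to_numpy()
            rate = y[m].sum() / totals[m].sum()
            mu[m] = rate * totals[m]
        alpha = _mom_dispersion(y, mu)
        fam = sm.families.NegativeBinomial(alpha=alpha)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=200)
            coef, se = fit.params[1], fit.bse[1]
        except Exception:  # perfect separation / zero group
            coef, se = np.nan, np.nan
        if np.isfinite(coef) and np.isfinite(se) and se > 0:
            z = coef / se
            p = 2.0 * norm.sf(abs(z))
        else:
            p = 1.0
        rows.append({
            "segment": v,
            "count_a": int(counts[v][grp == ga].sum()),
            "count_b": int(counts[v][grp == gb].sum()),
            "lfc": float(coef / np.log(2)) if np.isfinite(coef) else np.nan,
            "p": float(p),
            "frequency_class": "high" if pooled_fraction[v] > high_frequency_threshold
                               else "low",
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def unique_v_fraction(table: pd.DataFrame, segment: str,
                      key_mode: str = "nt") -> pd.Series:
    """Per-sample fraction of unique clonotypes carrying ``segment``."""
    cols = _key_columns(key_mode)
    if "v_call" not in cols:
        cols = ["v_call"] + cols
    uniq = table.drop_duplicates(subset=["sample_id"] + cols)
    out = {}
    for sample, grp in uniq.groupby("sample_id", sort=True):
        if len(grp) == 0:
            raise ValueError(f"sample {sample} has no clonotypes")
        out[sample] = float((grp["v_call"] == segment).mean())
    if not out:
        raise ValueError("empty clonotype table")
    return pd.Series(out, name=f"unique_fraction_{segment}")


def _ranked_unique(table_sample: pd.DataFrame, key_mode: str) -> pd.DataFrame:
    cols = _key_columns(key_mode)
    if "v_call" not in cols:
        cols = ["v_call"] + cols
    uniq = (table_sample.groupby(cols, sort=True)["count"].sum()
            .reset_index().sort_values(["count"] + cols,
                                       ascending=[False] + [True] * len(cols)))
    return uniq.reset_index(drop=True)


def top_expanded_v_fraction(table: pd.DataFrame, segment: str, n: int = 100,
                            key_mode: str = "nt") -> pd.DataFrame:
    """Per-sample fraction of the ``n`` most expanded clonotypes carrying
    ``segment``; ties broken by key order. Samples with fewer than ``n``
    clonotypes use all of them and are flagged."""
    rows = []
    for sample, grp in table.groupby("sample_id", sort=True):
        uniq = _ranked_unique(grp, key_mode)
        flagged = len(uniq) < n
        if flagged:
            log.warning("sample %s has %d < %d clonotypes; using all",
                        sample, len(uniq), n)
        top = uniq.head(n)
        rows.append({"sample_id": sample,
                     "fraction": float((top["v_call"] == segment).mean()),
                     "n_used": len(top), "truncated": flagged})
    return pd.DataFrame(rows)


def quintile_enrichment(table: pd.DataFrame, segment: str,
                        key_mode: str = "nt") -> pd.DataFrame:
    """Fisher test of segment membership vs top-quintile expansion, per sample.

    Unique clonotypes are ranked by template count (descending, ties by key);
    the top fifth of ranks forms the top quintile. The odds ratio is reported
    missing (with a note) when undefined.
    """
    rows = []
    for sample, grp in table.groupby("sample_id", sort=True):
        uniq = _ranked_unique(grp, key_mode)
        n = len(uniq)
        if n < 5:
            raise ValueError(f"sample {sample} has {n} < 5 unique clonotypes")
        n_top = max(1, n // 5)
        in_top = np.zeros(n, dtype=bool)
        in_top[:n_top] = True
        has_seg = (uniq["v_call"] == segment).to_numpy()
        a = int((in_top & has_seg).sum())
        b = int((in_top & ~has_seg).sum())
        c = int((~in_top & has_seg).sum())
        d = int((~in_top & ~has_seg).sum())
        oddsratio, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        note = ""
        if b == 0 and c == 0 or not np.isfinite(oddsratio):
            oddsratio, note = np.nan, "odds ratio undefined (zero margin)"
        rows.append({"sample_id": sample, "n_top": a + b, "n_rest": c + d,
                     "top_with_segment": a, "rest_with_segment": c,
                     "odds_ratio": oddsratio, "p": float(p), "note": note})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CDR3 composition

def cdr3_aa_usage(table: pd.DataFrame, group_by: str = "condition",
                  groups: Optional[tuple[str, str]] = None,
                  germline_prefix_len: int = 3,
                  germline_suffix_len: int = 1) -> pd.DataFrame:
    """Amino-acid usage of unique CDR3s per group, with per-residue tests.

    Reports global frequencies and frequencies restricted to non-germline
    positions (those outside the declared V prefix / J suffix). When two
    groups are named, a two-proportion z-test per residue (on global usage)
    with BH correction is added.
    """
    uniq = table.drop_duplicates(subset=["sample_id", "v_call", "cdr3_aa"])
    bad = uniq["cdr3_aa"].str.contains(f"[^{AA_ALPHABET}]", regex=True)
    if bad.any():
        raise ValueError(
            f"non-amino-acid characters in CDR3: {uniq.loc[bad, 'cdr3_aa'].iloc[0]!r}")

    def _freqs(seqs: pd.Series) -> tuple[pd.Series, pd.Series, int, int]:
        all_chars, core_chars = [], []
        for s in seqs:
            all_chars.append(s)
            core = s[germline_prefix_len: len(s) - germline_suffix_len]
            core_chars.append(core)
        glob = pd.Series(list("".join(all_chars))).value_counts()
        core = pd.Series(list("".join(core_chars))).value_counts()
        return glob, core, int(glob.sum()), int(core.sum())

    out = []
    group_counts: dict[str, tuple[pd.Series, int]] = {}
    for g, grp in uniq.groupby(group_by, sort=True):
        glob, core, n_glob, n_core = _freqs(grp["cdr3_aa"])
        group_counts[g] = (glob, n_glob)
        for aa in AA_ALPHABET:
            out.append({
                "group": g, "residue": aa,
                "global_freq": glob.get(aa, 0) / n_glob if n_glob else 0.0,
                "nongermline_freq": core.get(aa, 0) / n_core if n_core else 0.0,
            })
    result = pd.DataFrame(out)
    if groups is not None:
        ga, gb = groups
        (ca, na), (cb, nb) = group_counts[ga], group_counts[gb]
        ps = []
        for aa in AA_ALPHABET:
            x = np.array([ca.get(aa, 0), cb.get(aa, 0)])
            n = np.array([na, nb])
            p_pool = x.sum() / n.sum()
            se = np.sqrt(p_pool * (1 - p_pool) * (1 / n[0] + 1 / n[1]))
            z = (x[0] / n[0] - x[1] / n[1]) / se if se > 0 else 0.0
            ps.append(2.0 * norm.sf(abs(z)))
        tests = pd.DataFrame({"residue": list(AA_ALPHABET), "p": ps})
        tests["q"] = multipletests(tests["p"], method="fdr_bh")[1]
        result = result.merge(tests, on="residue", how="left")
    return result


def motif_frequency(table: pd.DataFrame, motif_pattern: str,
                    key_mode: str = "nt") -> pd.Series:
    """Per-sample fraction of unique clonotypes whose CDR3 matches the motif."""
    try:
        pattern = re.compile(motif_pattern)
    except re.error as exc:
        raise ValueError(f"invalid motif pattern {motif_pattern!r}: {exc}") from exc
    cols = _key_columns(key_mode)
    if "cdr3_aa" not in cols:
        cols = cols + ["cdr3_aa"]
    uniq = table.drop_duplicates(subset=["sample_id"] + cols)
    out = {}
    for sample, grp in uniq.groupby("sample_id", sort=True):
        out[sample] = float(grp["cdr3_aa"].apply(
            lambda s: bool(pattern.search(s))).mean())
    return pd.Series(out, name="motif_fraction")


# ---------------------------------------------------------------------------
# sharing

def sharing(table: pd.DataFrame, key_mode: str = "nt") -> pd.DataFrame:
    """Pairwise clonotype sharing between samples.

    Per sample pair: number of shared unique keys, Jaccard index, and the
    mean amino-acid length of shared CDR3s (missing when disjoint). Pairs are
    classed ``within-<condition>`` or ``between``.
    """
    cols = _key_columns(key_mode)
    sample_cond = table.groupby("sample_id")["condition"].first()
    keysets: dict[str, set] = {}
    aa_len: dict[tuple, float] = {}
    for sample, grp in table.groupby("sample_id", sort=True):
        ks = set(map(tuple, grp[cols].itertuples(index=False, name=None)))
        keysets[sample] = ks
        for key, aa in zip(map(tuple, grp[cols].itertuples(index=False, name=None)),
                           grp["cdr3_aa"]):
            aa_len.setdefault(key, len(aa))
    samples = sorted(keysets)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    rows = []
    for s1, s2 in combinations(samples, 2):
        shared = keysets[s1] & keysets[s2]
        union = keysets[s1] | keysets[s2]
        c1, c2 = sample_cond[s1], sample_cond[s2]
        rows.append({
            "sample_a": s1, "sample_b": s2,
            "shared": len(shared), "jaccard": len(shared) / len(union),
            "mean_shared_length": (float(np.mean([aa_len[k] for k in shared]))
                                   if shared else np.nan),
            "pair_class": f"within-{c1}" if c1 == c2 else "between",
        })
    return pd.DataFrame(rows)


def segment_usage_summary(table: pd.DataFrame, locus: str) -> pd.DataFrame:
    """Per-segment per-sample unique-clonotype fractions for one locus prefix
    (e.g. ``TRBV``, ``TRGV``); fractions sum to 1 per sample."""
    sub = table[table["v_call"].str.startswith(locus)]
    if sub.empty:
        raise ValueError(f"no clonotypes with V call in locus {locus!r}")
    uniq = sub.drop_duplicates(subset=["sample_id", "v_call", "cdr3_nt", "cdr3_aa"])
    rows = []
    for sample, grp in uniq.groupby("sample_id", sort=True):
        fracs = grp["v_call"].value_counts(normalize=True)
        for seg, f in fracs.sort_index().items():
            rows.append({"sample_id": sample,
                         "condition": grp["condition"].iloc[0],
                         "segment": seg, "fraction": float(f)})
    return pd.DataFrame(rows)
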