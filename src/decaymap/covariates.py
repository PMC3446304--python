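"""Covariate analysis of half-life and expression determinants.

Gene-level factors (expression, G+C percentage, operon size, functional
class, RBS composition, repeat co-transcription, stem-loop counts, ...) are
tested against log-transformed half-life or expression. The main engine is
a cyclic ANOVA: for every factor, the response is first regressed on all
*other* factors and the factor of interest is then tested against the
residuals — a numeric factor by a Pearson correlation test (a partial
correlation), a categorical one by a one-way F-test. Class-level post-hoc
contrasts use Welch's t-test on log half-lives with a fixed alpha of 0.005
and a minimum class size of more than 25 — the multiple-testing convention
adopted here in place of FDR machinery.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .models import STATUS_OK, GeneRecord, HalfLifeRecord, TranscriptionalUnit

_VALID_BASES = set("ACGT")
# 3' tail of the 16S rRNA that pairs with the ribosome binding site, written
# as DNA 3'->5' so it aligns index-by-index with the mRNA window 5'->3'
# (the canonical AGGAG window pairs at every position).
DEFAULT_ANTI_SD = "TCCTC"
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}


# ---------------------------------------------------------------------------
# table assembly


def build_table(genes: list[GeneRecord], expression: pd.DataFrame,
                records: list[HalfLifeRecord],
                tus: list[TranscriptionalUnit] | None = None,
                scale_numeric: bool = True) -> pd.DataFrame:
    """Join per-gene covariates with fitted half-lives.

    Only genes with status 'ok' are kept (capped genes enter at the cap).
    Half-life and expression are log-transformed; with ``scale_numeric``
    numeric covariates are divided by their standard deviation so all
    factors are on comparable scales.

    ``expression`` is the tidy table with columns gene_id, time_min,
    rpk_raw (t0 rows give the expression covariate).
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in annotation")
    ok = {r.gene_id: r for r in records if r.status == STATUS_OK}
    expr0 = (expression[expression["time_min"] == 0.0]
             .groupby("gene_id")["rpk_raw"].mean())
    operon_size: dict[str, int] = {}
    repeat_flag: dict[str, bool] = {}
    if tus is not None:
        for tu in tus:
            for gid in tu.member_gene_ids:
                operon_size[gid] = tu.n_members
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for gid, rec in ok.items():
        g = by_id.get(gid)
        if g is None or gid not in expr0.index or expr0[gid] <= 0:
            continue
        rbs = rbs_pairing_factors(g.rbs_sequence) if g.rbs_sequence else None
        rows.append({
            "gene_id": gid,
            "half_life_min": rec.half_life,
            "capped": rec.capped,
            "log_half_life": np.log(rec.half_life),
            "log_expression": np.log(expr0[gid]),
            "gc_percent": g.gc_fraction * 100.0,
            "cog_class": g.cog_class or "none",
            "n_genes_in_operon": operon_size.get(gid, 1),
            "rbs_base2": rbs["base2"] if rbs else None,
            "rbs_last": rbs["last_base"] if rbs else None,
            "repeat_cotranscribed": bool(g.repeat_families)
                                    or repeat_flag.get(gid, False),
            "gene_length": g.length,
        })
    table = pd.DataFrame(rows)
    if scale_numeric and len(table):
        for col in ("log_half_life", "log_expression", "gc_percent",
                    "n_genes_in_operon", "gene_length"):
            sd = table[col].std()
            if sd > 0:
                table[col + "_scaled"] = table[col] / sd
    return table


# ---------------------------------------------------------------------------
# cyclic ANOVA


def _design_matrix(table: pd.DataFrame, factors: list[str]) -> np.ndarray:
    cols = [np.ones(len(table))]
    for f in factors:
        col = table[f]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(col.astype(str), drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _drop_aliased(table: pd.DataFrame, factors: list[str]) -> list[str]:
    """Drop factors that add no rank to the design (aliased), with a warning."""
    kept: list[str] = []
    for f in factors:
        X = _design_matrix(table, kept + [f])
        if np.linalg.matrix_rank(X) > np.linalg.matrix_rank(_design_matrix(table, kept)):
            kept.append(f)
        else:
            warnings.warn(f"factor {f!r} is aliased with earlier factors; dropped")
    return kept


def cyclic_anova(table: pd.DataFrame, response: str,
                 factors: list[str]) -> pd.DataFrame:
    """Residualized single-factor tests, cycling over the factor list.

    For each factor F the response is regressed (least squares, categorical
    factors as indicator columns) on every *other* factor; F is then tested
    against the residuals. Numeric factors report the partial Pearson
    correlation and its p-value; categorical factors a one-way ANOVA F-test
    across levels. Aliased factors are dropped with a warning.
    """
    if len(factors) < 2:
        raise ValueError("need at least two factors")
    sub = table.dropna(subset=[response] + factors)
    factors = _drop_aliased(sub, factors)
    y = sub[response].to_numpy(dtype=float)
    results = []
    for f in factors:
        others = [o for o in factors if o != f]
        X = _design_matrix(sub, others)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        col = sub[f]
        if pd.api.types.is_numeric_dtype(col):
            r, p = stats.pearsonr(resid, col.to_numpy(dtype=float))
            results.append({"factor": f, "p_value": float(p),
                            "correlation": float(r), "n": len(sub),
                            "kind": "numeric"})
        else:
            groups = [resid[(col == level).to_numpy()]
                      for level in col.unique()]
            groups = [g for g in groups if len(g) > 1]
            if len(groups) < 2:
                continue
            stat, p = stats.f_oneway(*groups)
            results.append({"factor": f, "p_value": float(p),
                            "correlation": np.nan, "n": len(sub),
                            "kind": "categorical"})
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# post-hoc class contrasts


def posthoc_class_test(table: pd.DataFrame, class_label: str,
                       min_n: int = 25, alpha: float = 0.005,
                       include_capped: bool = True) -> pd.DataFrame:
    """Per-level Welch contrasts of log half-life: level vs all other genes.

    Levels with strictly more than ``min_n`` members are tested; reported
    means are arithmetic means of the raw half-lives in minutes. Capped
    genes participate at the cap value unless ``include_capped=False``.
    """
    sub = table if include_capped else table[~table["capped"]]
    sub = sub.dropna(subset=[class_label, "log_half_life"])
    results = []
    for level in sorted(sub[class_label].astype(str).unique()):
        mask = (sub[class_label].astype(str) == level).to_numpy()
        n = int(mask.sum())
        if n <= min_n or (~mask).sum() < 2:
            continue
        in_log = sub.loc[mask, "log_half_life"]
        out_log = sub.loc[~mask, "log_half_life"]
        stat, p = stats.ttest_ind(in_log, out_log, equal_var=False)
        results.append({
            "level": level, "n": n,
            "mean_half_life": float(sub.loc[mask, "half_life_min"].mean()),
            "mean_half_life_others": float(sub.loc[~mask, "half_life_min"].mean()),
            "p_value": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(results,
                        columns=["level", "n", "mean_half_life",
                                 "mean_half_life_others", "p_value",
                                 "significant"])


# ---------------------------------------------------------------------------
# sequence-attribute factors


def gc_adjust(expression, gc_percent):
    """Platform G+C-bias adjustment of expression.

    For genes with G+C between 30 and 40 percent (inclusive):
    Exp_adj = Exp x (G+C% x -0.05 + 2.5), a linear ramp that halves the
    measured expression at 40% G+C and leaves 30% unchanged. Outside that
    window expression is returned as-is.
    """
    expression = np.asarray(expression, dtype=float)
    gc = np.asarray(gc_percent, dtype=float)
    factor = np.where((gc >= 30) & (gc <= 40), gc * -0.05 + 2.5, 1.0)
    out = expression * factor
    if out.ndim == 0:
        return float(out)
    return out


def rbs_pairing_factors(rbs_sequence: str | None,
                        anti_sd: str = DEFAULT_ANTI_SD) -> dict | None:
    """RBS composition factors from the 16S-pairing window.

    The window is the first five positions of the last six bases of the RBS
    (the stretch that base-pairs with the 3' tail of 16S rRNA). Emits the
    2nd and last base of the window and per-position canonical-pairing flags
    against the anti-Shine-Dalgarno sequence. Sequences shorter than five
    bases or containing non-ACGT characters are excluded (None).
    """
    if not rbs_sequence:
        return None
    seq = rbs_sequence.upper()
    if len(seq) < 5 or not set(seq) <= _VALID_BASES:
        return None
    window = seq[-6:-1] if len(seq) >= 6 else seq[:5]
    paired = tuple(_WC[b] == a for b, a in zip(window, anti_sd[:5]))
    return {
        "window": window,
        "base2": window[1],
        "last_base": window[-1],
        "paired": paired,
        "n_paired": sum(paired),
    }


ENERGY_BINS = (-5.0, -7.0, -9.0, -11.0)
DOWNSTREAM_LENGTHS = (7, 9, 11)
GC_COUNTS = (0, 1, 2)


def bin_stem_loops(candidates: pd.DataFrame, genes: list[GeneRecord],
                   nested: bool = True) -> pd.DataFrame:
    """Per-gene counts of candidate stem-loop sites in 36 energy groups.

    Candidates carry columns position, folding_energy (kcal/mol),
    downstream_len (7/9/11 nt) and downstream_gc_count (0/1/2). Groups are
    the product of four folding-energy thresholds (lower than -5/-7/-9/-11;
    nested by default, so a -12 kcal/mol site counts in all four), the
    downstream length, and the downstream G+C count. A site is assigned to
    the gene whose CDS contains its position (position only — the data are
    unstranded).
    """
    columns = [f"sl_lt{int(-e)}_len{l}_gc{c}"
               for e in ENERGY_BINS for l in DOWNSTREAM_LENGTHS for c in GC_COUNTS]
    counts = pd.DataFrame(0, index=[g.gene_id for g in genes], columns=columns)
    counts.index.name = "gene_id"
    if len(candidates) == 0:
        return counts.reset_index()
    ordered = sorted(genes, key=lambda g: (g.replicon, g.start))
    for row in candidates.itertuples(index=False):
        gene = next((g for g in ordered
                     if g.start <= row.position < g.end), None)
        if gene is None:
            continue
        if row.downstream_len not in DOWNSTREAM_LENGTHS \
                or row.downstream_gc_count not in GC_COUNTS:
            continue
        if nested:
            bins = [e for e in ENERGY_BINS if row.folding_energy < e]
        else:
            passed = [e for e in ENERGY_BINS if row.folding_energy < e]
            bins = [min(passed)] if passed else []
        for e in bins:
            col = (f"sl_lt{int(-e)}_len{row.downstream_len}"
                   f"_gc{row.downstream_gc_count}")
            counts.loc[gene.gene_id, col] += 1
    return counts.reset_index()
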