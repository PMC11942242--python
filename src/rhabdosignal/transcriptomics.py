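"""Two-group differential expression and gene-set enrichment.

Differential expression uses a moderated t-statistic: per-gene pooled
variances s_g^2 (d_g residual df) are shrunk toward a prior s0^2 with
prior df d0,

    s_post^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t_g      = logFC_g / (s_post * sqrt(1/n1 + 1/n2)),   df = d0 + d_g.

The hyperparameters (d0, s0^2) are estimated by moment-matching the
observed variance distribution against a scaled F on the log scale
(digamma/trigamma matching), i.e. the classic empirical-Bayes fit for a
scaled inverse-chi-square prior. d0 = 0 recovers the ordinary t test;
d0 = inf gives a z-like statistic with the common prior variance.

Genes are called up/down at BH-adjusted p < alpha and |log2 fold change|
>= fc_threshold (defaults 0.05 and 1.5). Enrichment is a one-sided
hypergeometric test with fold enrichment (k/n)/(K/N), BH-adjusted across
sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from rhabdosignal.errors import ConfigError, RhabdosignalError


@dataclass
class ExpressionMatrix:
    """A genes x samples log-scale expression matrix with two groups.

    ``data`` rows are unique gene symbols; ``groups`` maps every sample
    (column) to a group label; ``treatment``/``control`` name the contrast.
    """

    data: pd.DataFrame
    groups: Mapping[str, str]
    treatment: str = "treatment"
    control: str = "control"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ConfigError("duplicate gene symbols in expression matrix")
        missing = [s for s in self.data.columns if s not in self.groups]
        if missing:
            raise ConfigError(f"samples without group assignment: {missing}")
        for group in (self.treatment, self.control):
            if len(self.samples_in(group)) < 2:
                raise ConfigError(
                    f"group {group!r} needs >= 2 replicates for variance estimation"
                )

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == group]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the log scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return x


def fit_variance_prior(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (prior_df d0, prior_var s0^2) on log sample variances.

    Fits s_g^2 ~ s0^2 * F(df, d0): on the log scale the mean and variance
    of log F are digamma/trigamma expressions, so matching the empirical
    moments gives d0 via a trigamma inverse. Zero variances are excluded
    from the fit (they are later assigned the prior variance).
    """
    x = np.asarray(variances, dtype=float)
    x = x[x > 0]
    if x.size < 2:
        raise ConfigError("need >= 2 positive gene variances to fit the prior")
    z = np.log(x)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s0_sq = math.exp(e_mean)
    return d0, s0_sq


def differential_expression(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 1.5,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated-t differential expression between treatment and control.

    Returns one row per gene with columns ``gene, log_fc, moderated_t,
    p_value, adj_p, call`` (call in {up, down, not_significant}).
    ``prior_df`` overrides the estimated d0: 0 gives the ordinary t test,
    ``inf`` the fully shrunk z-like statistic.
    """
    treat = matrix.samples_in(matrix.treatment)
    ctrl = matrix.samples_in(matrix.control)
    n1, n2 = len(treat), len(ctrl)
    y1 = matrix.data[treat].to_numpy(dtype=float)
    y2 = matrix.data[ctrl].to_numpy(dtype=float)

    log_fc = y1.mean(axis=1) - y2.mean(axis=1)
    ss = y1.var(axis=1, ddof=1) * (n1 - 1) + y2.var(axis=1, ddof=1) * (n2 - 1)
    d_g = n1 + n2 - 2
    s_sq = ss / d_g

    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s_sq, d_g)
    elif prior_df == 0:
        d0, s0_sq = 0.0, float(np.median(s_sq[s_sq > 0])) if (s_sq > 0).any() else 1.0
    else:
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s_sq, d_g)

    if math.isinf(d0):
        s_post = np.full_like(s_sq, s0_sq)
        df_total = math.inf
    else:
        s_post = (d0 * s0_sq + d_g * s_sq) / (d0 + d_g)
        df_total = d0 + d_g
    # constant rows: fall back to the prior variance so t stays finite
    s_post = np.where(s_post > 0, s_post, s0_sq if s0_sq > 0 else 1e-12)

    se = np.sqrt(s_post * (1.0 / n1 + 1.0 / n2))
    t_stat = log_fc / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    adj = benjamini_hochberg(p)

    call = np.full(len(log_fc), "not_significant", dtype=object)
    call[(adj < alpha) & (log_fc >= fc_threshold)] = "up"
    call[(adj < alpha) & (log_fc <= -fc_threshold)] = "down"

    return pd.DataFrame(
        {
            "gene": matrix.data.index,
            "log_fc": log_fc,
            "moderated_t": t_stat,
            "p_value": p,
            "adj_p": adj,
            "call": call,
        }
    ).reset_index(drop=True)


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise RhabdosignalError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def count_de_genes(results: pd.DataFrame) -> tuple[int, int, int]:
    """(n_total, n_up, n_down) differentially expressed genes."""
    if len(results) == 0:
        return (0, 0, 0)
    n_up = int((results["call"] == "up").sum())
    n_down = int((results["call"] == "down").sum())
    return (n_up + n_down, n_up, n_down)


def log_cpm(counts: pd.DataFrame, offset: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a small offset, for raw count input."""
    lib = counts.sum(axis=0)
    return np.log2((counts + offset).div(lib + 1.0, axis=1) * 1e6)


def read_expression(matrix_path: str | Path, groups_path: str | Path,
                    treatment: str = "treatment", control: str = "control",
                    ) -> ExpressionMatrix:
    """Load a tab-delimited gene x sample matrix plus a sample-to-group file."""
    data = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t", header=None,
                            names=["sample", "group"])
    groups = dict(zip(groups_df["sample"].astype(str), groups_df["group"].astype(str)))
    return ExpressionMatrix(data=data, groups=groups,
                            treatment=treatment, control=control)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     groups_path: str | Path) -> None:
    matrix.data.to_csv(matrix_path, sep="\t")
    with open(groups_path, "w", encoding="utf-8") as fh:
        for sample in matrix.data.columns:
            fh.write(f"{sample}\t{matrix.groups[sample]}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: one set per line, ``name<TAB>desc<TAB>gene...``."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def enrich(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each gene set.

    Sets are intersected with the background before testing; p is the
    upper tail P(hits >= k); fold enrichment is (k/n)/(K/N); FDR is BH
    across the tested sets. Empty-overlap sets report fold 0 and p 1.
    Returns rows sorted by ascending p.
    """
    bg = set(background)
    hits = set(gene_list) & bg
    if not bg:
        raise ConfigError("empty background universe")
    if not hits:
        raise ConfigError("empty gene list (after background intersection)")
    n, big_n = len(hits), len(bg)

    rows = []
    for name, members in gene_sets.items():
        in_bg = members & bg
        big_k = len(in_bg)
        overlap = sorted(hits & in_bg)
        k = len(overlap)
        if big_k == 0:
            continue
        if k == 0:
            fold, p = 0.0, 1.0
        else:
            fold = (k / n) / (big_k / big_n)
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "set_name": name, "k": k, "K": big_k, "n": n, "N": big_n,
                "fold_enrichment": fold, "p_value": p,
                "gene_hits": ";".join(overlap),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = benjamini_hochberg(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "set_name"]).reset_index(drop=True)
    return out


__all__ = [
    "ExpressionMatrix",
    "fit_variance_prior",
    "differential_expression",
    "benjamini_hochberg",
    "count_de_genes",
    "log_cpm",
    "read_expression",
    "write_expression",
    "read_gmt",
    "enrich",
]
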