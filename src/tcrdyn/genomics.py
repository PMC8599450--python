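"""Tumor genomic metrics: CCF estimation, burden, wGII, ITH, neoantigen depletion.

The cancer cell fraction (CCF) of a mutation is inferred from its
variant allele frequency (VAF) through the purity/copy-number model

    VAF = CN_mut * CCF * p / (CN_n * (1 - p) + CN_t * p)

where p is tumour purity, CN_t the local tumour copy number, CN_n the
local copy number of the admixed normal cells (assumed 2) and CN_mut
the number of tumour copies carrying the mutation.  CCF and CN_mut are
fitted by exhaustive search over the grid CCF in {0.01, ..., 1.00}
(step 0.01) x CN_mut in {1, ..., CN_t}, minimising the absolute
difference between expected and observed VAF.

Burden metrics follow the standard definitions: TMB is exonic
non-synonymous SNVs per megabase of capture territory; the fsINDEL
burden is the count of exonic frameshift indels; the neoantigen burden
counts predicted strong binders (%rank < 0.5 mutant, > 0.5 wildtype).
Clonal burdens use ubiquitous mutations (present in every sample of a
patient) for multi-region cases and CCF > 0.5 for single-region cases.

wGII is the mean over the 22 autosomes of the fraction of covered
bases at a total copy number different from the rounded sample ploidy.
The ITH index is the ratio of subclonal to clonal driver alterations.

Selection against neoantigens is tested by classifying each mutation as
having undergone genomic contraction (CCF drop >= 0.10 from pre- to
post-treatment, or present pre and absent post) and applying a
one-sided Fisher exact test for enrichment of contraction among
neoantigen-encoding mutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

logger = logging.getLogger(__name__)

CCF_GRID = np.round(np.arange(1, 101) / 100.0, 2)  # 0.01 .. 1.00

#: purity assigned when the upstream purity solver falls below its
#: confidence threshold
PURITY_FALLBACK = 0.1

AUTOSOMES = tuple(str(c) for c in range(1, 23))


@dataclass(frozen=True)
class CCFFit:
    """Best-fit CCF/CN_mut pair from the exhaustive grid search.

    ``n_candidates`` counts grid points whose residual ties the
    minimum (within 1e-12); values above 1 flag a non-injective fit
    where the data cannot distinguish multiplicity/CCF combinations.
    """

    ccf: float
    cn_mut: int
    residual: float
    n_candidates: int

    @property
    def is_ambiguous(self) -> bool:
        return self.n_candidates > 1


def expected_vaf(
    ccf: float, cn_mut: int, purity: float, cn_tumor: int, cn_normal: int = 2
) -> float:
    """Expected VAF under the purity/copy-number mixture model."""
    denom = cn_normal * (1.0 - purity) + cn_tumor * purity
    if denom <= 0:
        raise ValueError("degenerate copy-number state: zero expected total coverage")
    return cn_mut * ccf * purity / denom


def estimate_ccf(
    vaf: float, purity: float, cn_tumor: int, cn_normal: int = 2
) -> CCFFit:
    """Exhaustive grid search for the best-fit (CCF, CN_mut).

    Ties in |expected - observed| are broken by smaller CN_mut, then
    smaller CCF (the most parsimonious state).
    """
    if cn_tumor < 1:
        raise ValueError("no mutated copy possible with cn_tumor < 1")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must lie in [0, 1]")
    cn_mut_grid = np.arange(1, cn_tumor + 1)
    exp = (
        cn_mut_grid[:, None]
        * CCF_GRID[None, :]
        * purity
        / (cn_normal * (1.0 - purity) + cn_tumor * purity)
    )
    resid = np.abs(exp - vaf)
    best = resid.min()
    ties = resid <= best + 1e-12
    n_candidates = int(ties.sum())
    # row-major argmax over the tie mask = smallest cn_mut, then smallest ccf
    i, j = np.unravel_index(int(np.argmax(ties)), ties.shape)
    return CCFFit(
        ccf=float(CCF_GRID[j]),
        cn_mut=int(cn_mut_grid[i]),
        residual=float(resid[i, j]),
        n_candidates=n_candidates,
    )


def annotate_ccf(
    mutations: pd.DataFrame, purity: dict[str, float] | float, cn_normal: int = 2
) -> pd.DataFrame:
    """Add ccf/cn_mut/ccf_residual/ccf_ambiguous columns to a mutation table.

    ``mutations`` needs columns sample_id, vaf, cn_tumor; ``purity`` is a
    scalar or a sample_id -> purity mapping.
    """
    out = mutations.copy()
    ccfs, cnms, resids, ambig = [], [], [], []
    for row in out.itertuples(index=False):
        p = purity[row.sample_id] if isinstance(purity, dict) else purity
        fit = estimate_ccf(float(row.vaf), p, int(row.cn_tumor), cn_normal)
        ccfs.append(fit.ccf)
        cnms.append(fit.cn_mut)
        resids.append(fit.residual)
        ambig.append(fit.is_ambiguous)
    out["ccf"] = ccfs
    out["cn_mut"] = cnms
    out["ccf_residual"] = resids
    out["ccf_ambiguous"] = ambig
    return out


def classify_strong_binders(predictions: pd.DataFrame) -> pd.Series:
    """Boolean strong-binder mask: %rank < 0.5 mutant and > 0.5 wildtype."""
    return (predictions["rank_mutant"] < 0.5) & (predictions["rank_wildtype"] > 0.5)


def burden_metrics(mutations: pd.DataFrame, exome_mb: float) -> pd.DataFrame:
    """Per-sample burden metrics for one patient's mutation table.

    Requires columns: sample_id, mutation_id, mutation_class
    ({nsSNV, fsINDEL, other}), is_exonic, is_neoantigen_encoding and,
    for single-region patients, ccf.  ``exome_mb`` is the capture
    territory in megabases and must be supplied explicitly.
    """
    if exome_mb is None or exome_mb <= 0:
        raise ValueError("exome_mb (capture territory, Mb) is required and must be > 0")
    samples = sorted(mutations["sample_id"].unique())
    multiregion = len(samples) > 1
    if multiregion:
        # ubiquitous = present in every sample of the patient
        presence = mutations.groupby("mutation_id")["sample_id"].nunique()
        ubiquitous = set(presence[presence == len(samples)].index)
    rows = []
    for sid in samples:
        sub = mutations[mutations["sample_id"] == sid]
        ns = sub[(sub["mutation_class"] == "nsSNV") & sub["is_exonic"]]
        fs = sub[(sub["mutation_class"] == "fsINDEL") & sub["is_exonic"]]
        if multiregion:
            ns_clonal = ns[ns["mutation_id"].isin(ubiquitous)]
            fs_clonal = fs[fs["mutation_id"].isin(ubiquitous)]
        else:
            ns_clonal = ns[ns["ccf"] > 0.5]
            fs_clonal = fs[fs["ccf"] > 0.5]
        rows.append(
            {
                "sample_id": sid,
                "tmb": len(ns) / exome_mb,
                "fsindel_count": len(fs),
                "neoantigen_count": int(sub["is_neoantigen_encoding"].sum()),
                "clonal_tmb": len(ns_clonal) / exome_mb,
                "clonal_fsindel": len(fs_clonal),
            }
        )
    return pd.DataFrame(rows)


def wgii(segments: pd.DataFrame, ploidy: float) -> float | None:
    """Weighted genome instability index of one sample.

    ``segments`` needs columns chromosome, start, end, total_cn.  Per
    autosome, the fraction of covered bases whose total copy number
    differs from round(ploidy); wGII is the mean of those fractions.
    Autosomes without segments are excluded from the mean with a
    warning; returns None when no autosomal segment exists.
    """
    ref = int(round(ploidy))
    fractions = []
    missing = []
    seg = segments.copy()
    seg["chromosome"] = seg["chromosome"].astype(str).str.removeprefix("chr")
    for chrom in AUTOSOMES:
        sub = seg[seg["chromosome"] == chrom]
        if len(sub) == 0:
            missing.append(chrom)
            continue
        lengths = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        if (lengths <= 0).any():
            raise ValueError("segments must satisfy end > start")
        aberrant = (sub["total_cn"].to_numpy() != ref).astype(float)
        fractions.append(float((lengths * aberrant).sum() / lengths.sum()))
    if missing:
        logger.warning("wGII: no segments on chromosomes %s; excluded from mean", missing)
    if not fractions:
        return None
    return float(np.mean(fractions))


def ith_index(n_subclonal: int, n_clonal: int) -> float | None:
    """Intratumour-heterogeneity index: subclonal / clonal driver count.

    Undefined (None) when no clonal driver exists.
    """
    if n_clonal == 0:
        return None
    return n_subclonal / n_clonal


@dataclass(frozen=True)
class DepletionTestResult:
    """Genomic-contraction enrichment among neoantigen-encoding mutations."""

    labels: pd.DataFrame
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float | None
    p_value: float | None


def neoantigen_depletion_test(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    drop_threshold: float = 0.10,
    relative: bool = False,
    alternative: str = "greater",
) -> DepletionTestResult:
    """Test whether neoantigen-encoding mutations preferentially contract.

    ``pre`` and ``post`` need columns mutation_id, ccf,
    is_neoantigen_encoding; multiple pre-treatment samples should be
    summarised by their median CCF per mutation beforehand (see
    :func:`median_ccf_baseline`).  A mutation contracts when its CCF
    drops by >= ``drop_threshold`` (absolute CCF units by default,
    relative fraction of baseline when ``relative=True``) or when it is
    present pre-treatment but absent post-treatment.  Enrichment is the
    Fisher exact test on (neoantigen-encoding vs other) x (contracted
    vs not), one-sided in the enrichment direction by default
    (``alternative='greater'``); pass ``alternative='two-sided'`` for
    the symmetric test.
    """
    post_ccf = post.set_index("mutation_id")["ccf"].to_dict()
    rows = []
    for row in pre.itertuples(index=False):
        ccf_post = post_ccf.get(row.mutation_id)
        if ccf_post is None:
            contracted = True
        elif relative:
            contracted = (row.ccf - ccf_post) >= drop_threshold * row.ccf
        else:
            contracted = (row.ccf - ccf_post) >= drop_threshold
        rows.append(
            {
                "mutation_id": row.mutation_id,
                "ccf_pre": row.ccf,
                "ccf_post": ccf_post,
                "is_neoantigen_encoding": bool(row.is_neoantigen_encoding),
                "contracted": bool(contracted),
            }
        )
    labels = pd.DataFrame(rows)
    neo = labels["is_neoantigen_encoding"]
    con = labels["contracted"]
    table = (
        (int((neo & con).sum()), int((neo & ~con).sum())),
        (int((~neo & con).sum()), int((~neo & ~con).sum())),
    )
    flat = [table[0][0], table[0][1], table[1][0], table[1][1]]
    row_margins = (flat[0] + flat[1], flat[2] + flat[3])
    col_margins = (flat[0] + flat[2], flat[1] + flat[3])
    if 0 in row_margins or 0 in col_margins:
        logger.info("depletion test: empty margin, p-value undefined; table still reported")
        return DepletionTestResult(labels=labels, table=table, odds_ratio=None, p_value=None)
    odds, p = fisher_exact(np.array(table), alternative=alternative)
    return DepletionTestResult(
        labels=labels, table=table, odds_ratio=float(odds), p_value=float(p)
    )


def median_ccf_baseline(pre_samples: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple pre-treatment samples to a median-CCF baseline.

    ``pre_samples`` has one row per (mutation_id, sample_id) with ccf
    and is_neoantigen_encoding; the result has one row per mutation.
    """
    grouped = pre_samples.groupby("mutation_id").agg(
        ccf=("ccf", "median"),
        is_neoantigen_encoding=("is_neoantigen_encoding", "any"),
    )
    return grouped.reset_index()


def signature_score(expression: pd.DataFrame, gene_set: list[str]) -> pd.Series | None:
    """Mean z-scored expression of a gene signature, per sample.

    ``expression`` is a genes x samples matrix of abundances; each gene
    is z-scored across samples before averaging over the signature's
    genes present in the matrix.  Missing genes are logged; returns
    None when no signature gene is present.
    """
    present = [g for g in gene_set if g in expression.index]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        logger.info("signature genes absent from matrix: %s", missing)
    if not present:
        return None
    sub = expression.loc[present].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    z = sub.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    return z.mean(axis=0)
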