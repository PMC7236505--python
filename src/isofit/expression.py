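"""Expression matrices: loading, TMM normalization, filtering, aggregation, usage.

The TMM recipe follows the classical published definition: per-sample scaling
factors from a weighted trimmed mean of M-values (30 % M-trim, 5 % A-trim,
reference = sample whose upper quartile is closest to the mean upper
quartile), factors rescaled to geometric mean 1, and values expressed as
counts-per-million of the effective library size (library size x factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from isofit.errors import AggregationError, ContractError, NormalizationError
from isofit.models import GeneModel


@dataclass
class ExpressionSet:
    """Transcript-by-sample expression with a two-group design."""

    values: pd.DataFrame  # rows = units (transcripts/genes/CDS), cols = samples
    design: pd.Series  # sample -> condition
    normalized: bool = False
    norm_factors: pd.Series | None = None
    effective_lib_size: pd.Series | None = None
    dropped_genes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (self.values.values < 0).any():
            raise ContractError("negative expression values")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ContractError(f"samples missing from design: {missing}")
        self.design = self.design.loc[list(self.values.columns)]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.design:
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        return list(self.design.index[self.design == condition])

    def require_two_groups(self):
        conds = self.conditions
        if len(conds) != 2:
            raise ContractError(f"expected exactly 2 conditions, got {conds}")
        for c in conds:
            if len(self.samples_of(c)) < 2:
                raise ContractError(f"condition {c!r} has fewer than 2 replicates")

    def condition_means(self) -> pd.DataFrame:
        """Per-unit mean over replicates for each condition."""
        return pd.DataFrame(
            {c: self.values[self.samples_of(c)].mean(axis=1) for c in self.conditions}
        )

    def subset(self, unit_ids) -> "ExpressionSet":
        return replace(self, values=self.values.loc[list(unit_ids)])


def load_expression(counts_path, design_path) -> ExpressionSet:
    """Read a TSV count matrix (first column = transcript_id) and a design TSV
    with columns ``sample`` and ``condition``."""
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    design_df = pd.read_csv(design_path, sep="\t")
    if not {"sample", "condition"} <= set(design_df.columns):
        raise ContractError("design file must have 'sample' and 'condition' columns")
    design = design_df.set_index("sample")["condition"]
    return ExpressionSet(values=values, design=design)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                m_trim: float = 0.30, a_trim: float = 0.05) -> float:
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    o, r = obs[keep], ref[keep]
    p_o, p_r = o / lib_obs, r / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # asymptotic (delta-method) binomial variance weights
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.allclose(m, m[0], atol=1e-10):
        return float(2 ** m[0])
    n = len(m)
    lo_m, hi_m = np.floor(n * m_trim) + 1, n - np.floor(n * m_trim)
    lo_a, hi_a = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any():
        return 1.0
    f = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    return float(2 ** f)


def tmm_factors(values: pd.DataFrame) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1."""
    lib = values.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise NormalizationError(f"all-zero sample(s): {bad}")
    frac = values / lib
    uq = frac.apply(lambda col: np.quantile(col[col > 0], 0.75) if (col > 0).any() else 0.0)
    ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = values[ref_sample].to_numpy(dtype=float)
    lib_ref = float(lib[ref_sample])
    factors = pd.Series(
        {
            s: _tmm_factor(values[s].to_numpy(dtype=float), ref, float(lib[s]), lib_ref)
            for s in values.columns
        }
    )
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    return factors


def normalize(raw: ExpressionSet) -> ExpressionSet:
    """TMM + sequencing-depth normalization to CPM of the effective library size."""
    if raw.normalized:
        raise ContractError("input is already normalized")
    lib = raw.values.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise NormalizationError(f"all-zero sample(s): {bad}")
    factors = tmm_factors(raw.values)
    eff = lib * factors
    cpm = raw.values / eff * 1e6
    return ExpressionSet(
        values=cpm,
        design=raw.design,
        normalized=True,
        norm_factors=factors,
        effective_lib_size=eff,
    )


def as_prenormalized(x: ExpressionSet) -> ExpressionSet:
    """Accept a pre-normalized matrix: unit factors, library sizes from column sums."""
    lib = x.values.sum(axis=0)
    return ExpressionSet(
        values=x.values,
        design=x.design,
        normalized=True,
        norm_factors=pd.Series(1.0, index=x.values.columns),
        effective_lib_size=lib,
    )


# ---------------------------------------------------------------------------
# filtering and aggregation
# ---------------------------------------------------------------------------

def filter_low_expression(
    x: ExpressionSet, min_cpm: float = 1.0, gene_map: pd.Series | None = None
) -> ExpressionSet:
    """Drop transcripts whose mean CPM is below ``min_cpm`` in *both* conditions.

    With a transcript->gene ``gene_map``, genes losing all transcripts are
    recorded on the result's ``dropped_genes``.
    """
    if not x.normalized:
        raise ContractError("filter_low_expression requires normalized input")
    means = x.condition_means()
    keep = (means >= min_cpm).any(axis=1)
    out = x.subset(x.values.index[keep])
    if gene_map is not None:
        gm = gene_map.reindex(x.values.index)
        before = set(gm.dropna())
        after = set(gm[keep].dropna())
        out.dropped_genes = sorted(before - after)
    return out


def gene_map_from_models(models: dict[str, GeneModel]) -> pd.Series:
    pairs = {
        t.transcript_id: g.gene_id
        for g in models.values()
        for t in g.transcripts
    }
    return pd.Series(pairs, name="gene_id")


def aggregate_expression(
    x: ExpressionSet, models: dict[str, GeneModel], level: str
) -> ExpressionSet:
    """Aggregate transcript expression to ``gene`` or ``cds`` level.

    Gene level sums all member transcripts (mass-conserving).  CDS level
    groups coding transcripts sharing identical genomic CDS intervals into one
    row (``<gene>:ORF<k>``); non-coding transcripts are excluded.
    """
    if level not in ("gene", "cds"):
        raise ContractError(f"unknown aggregation level {level!r}")
    transcripts = {
        t.transcript_id: t for g in models.values() for t in g.transcripts
    }
    missing = [tx for tx in x.values.index if tx not in transcripts]
    if missing:
        raise AggregationError(f"transcripts absent from models: {missing[:5]}")

    groups: dict[str, list[str]] = {}
    if level == "gene":
        for tx in x.values.index:
            groups.setdefault(transcripts[tx].gene_id, []).append(tx)
    else:
        orf_key: dict[tuple, str] = {}
        counter: dict[str, int] = {}
        for tx in x.values.index:
            t = transcripts[tx]
            if not t.is_coding:
                continue
            key = (t.gene_id, t.chrom, t.strand, tuple(t.cds_genomic_intervals()))
            if key not in orf_key:
                k = counter.get(t.gene_id, 0) + 1
                counter[t.gene_id] = k
                orf_key[key] = f"{t.gene_id}:ORF{k}"
            groups.setdefault(orf_key[key], []).append(tx)

    agg = pd.DataFrame(
        {gid: x.values.loc[members].sum(axis=0) for gid, members in groups.items()}
    ).T
    agg = agg[x.values.columns]
    return replace(x, values=agg, dropped_genes=[])


# ---------------------------------------------------------------------------
# isoform usage
# ---------------------------------------------------------------------------

@dataclass
class UsageTable:
    """Per-condition relative isoform usage within each gene.

    ``usage`` is transcript x condition; ``gene_of`` maps transcripts to
    genes; ``evaluable`` flags gene x condition cells with nonzero gene
    expression (usage is undefined elsewhere and stored as NaN).
    """

    usage: pd.DataFrame
    gene_of: pd.Series
    evaluable: pd.DataFrame

    def gene_usage(self, gene_id: str) -> pd.DataFrame:
        return self.usage.loc[self.gene_of[self.gene_of == gene_id].index]


def compute_usage(x: ExpressionSet, gene_map: pd.Series) -> UsageTable:
    """Usage = condition-mean isoform expression / condition-mean gene expression."""
    if not x.normalized:
        raise ContractError("compute_usage requires normalized input")
    means = x.condition_means()
    gm = gene_map.reindex(x.values.index)
    if gm.isna().any():
        raise AggregationError(
            f"transcripts without gene assignment: {list(gm.index[gm.isna()])[:5]}"
        )
    gene_tot = means.groupby(gm).sum()
    denom = gene_tot.loc[gm].set_axis(means.index)
    usage = means / denom.where(denom > 0)
    evaluable = gene_tot > 0
    return UsageTable(usage=usage, gene_of=gm, evaluable=evaluable)


def filter_minor_isoforms(
    x: ExpressionSet,
    gene_map: pd.Series,
    mode: str = "proportion",
    threshold: float | None = None,
) -> ExpressionSet:
    """Remove minor isoforms ahead of differential-usage testing.

    ``proportion``: drop isoforms with usage below ``threshold`` (default
    0.10) in all conditions.  ``foldchange``: drop isoforms whose
    per-condition major-isoform / isoform expression ratio is at least
    ``threshold`` (default 2) in all conditions.  The per-condition major
    isoform is never removed.
    """
    if not x.normalized:
        raise ContractError("filter_minor_isoforms requires normalized input")
    if mode not in ("proportion", "foldchange"):
        raise ContractError(f"unknown prefilter mode {mode!r}")
    if threshold is None:
        threshold = 0.10 if mode == "proportion" else 2.0
    if mode == "proportion" and not (0.0 < threshold < 1.0):
        raise ContractError("proportion threshold must lie in (0, 1)")

    means = x.condition_means()
    gm = gene_map.reindex(x.values.index)
    usage = compute_usage(x, gene_map).usage

    is_major = pd.DataFrame(False, index=means.index, columns=means.columns)
    for cond in means.columns:
        majors = (
            means[cond].groupby(gm).idxmax()
        )  # NaN-safe: all-zero genes give first index
        is_major.loc[majors.dropna(), cond] = True

    if mode == "proportion":
        minor = (usage.fillna(0.0) < threshold).all(axis=1)
    else:
        major_expr = means.where(is_major).groupby(gm).max()
        ratio = major_expr.loc[gm].set_axis(means.index) / means.where(means > 0)
        ratio = ratio.fillna(np.inf)
        minor = (ratio >= threshold).all(axis=1)
    drop = minor & ~is_major.any(axis=1)
    return x.subset(x.values.index[~drop])
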