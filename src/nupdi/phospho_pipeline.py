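"""DIA (SWATH-type) phosphoproteomics post-search processing.

Starts from an extracted precursor-level intensity matrix (samples
annotated with condition, replicate and timepoint) and runs the chain:

1. log2 transform + mean-centering normalization;
2. replicate filter — keep precursors seen in >= 2 of 3 replicates of at
   least one condition(-timepoint) triplicate;
3. two-branch missing-value imputation: draws centered on the triplicate
   mean when the triplicate has any observation, otherwise on a value
   threefold below the precursor's observed minimum (left-censoring
   emulation), both with SD equal to the mean within-triplicate SD;
4. protein-level summation (linear-scale) for non-enriched data;
5. phosphosite aggregation — median-merge monophosphorylated precursors
   per (protein, residue position), then split multiphosphorylated
   precursors into constituent sites kept only where no
   monophosphorylated evidence exists;
6. kinase-active vs. kinase-dead differential scoring: per-site mean
   log2 ratio over the post-induction window, empirical-Bayes moderated
   t statistics with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PrecursorTable",
    "SiteTable",
    "log2_and_center",
    "filter_by_replication",
    "impute_missing",
    "aggregate_protein",
    "merge_sites",
    "differential_phospho",
    "read_precursor_tsv",
    "write_precursor_tsv",
    "fit_variance_prior",
]

DEFAULT_WINDOW = (2.0, 3.0, 4.0, 5.0)
CANDIDATE_ALPHA = 0.01  # dark-dot class on the volcano plot
SCREEN_ALPHA = 0.05
SITE_RE = re.compile(r"^([A-Z])(\d+)$")
SAMPLE_RE = re.compile(r"^(?P<condition>[^_]+)_r(?P<replicate>\d+)_t(?P<tp>[0-9.]+)$")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def _validate_samples(samples: pd.DataFrame) -> None:
    required = {"condition", "replicate", "timepoint"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample annotation lacks columns: {sorted(missing)}")
    if samples[list(required)].isna().any().any():
        raise ValueError("sample annotations must not contain missing values")
    dup = samples.duplicated(subset=["condition", "replicate", "timepoint"])
    if dup.any():
        raise ValueError("duplicate (condition, replicate, timepoint) samples")


@dataclass
class PrecursorTable:
    """Sample x precursor intensity matrix with annotations.

    ``intensities``: rows = precursor ids, columns = sample ids; NaN marks
    a missing (undetected) value.  ``samples``: one row per sample id
    with condition / replicate / timepoint.  ``annotations``: one row per
    precursor with protein, phosphosite string (e.g. "S89" or
    "S371+S374") and localization-confidence tier.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    annotations: pd.DataFrame
    is_log2: bool = False

    def __post_init__(self) -> None:
        _validate_samples(self.samples)
        if not self.intensities.columns.equals(self.samples.index):
            if set(self.intensities.columns) != set(self.samples.index):
                raise ValueError("intensity columns and sample ids disagree")
            self.samples = self.samples.loc[self.intensities.columns]
        if not self.intensities.index.equals(self.annotations.index):
            if set(self.intensities.index) != set(self.annotations.index):
                raise ValueError("intensity rows and precursor annotations disagree")
            self.annotations = self.annotations.loc[self.intensities.index]
        vals = self.intensities.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("intensities must be finite where present")

    @property
    def n_precursors(self) -> int:
        return len(self.intensities)

    def triplicate_groups(self, pool_timepoints: bool = False):
        """Yield (key, sample-id list) for each condition(-timepoint) group."""
        cols = ["condition"] if pool_timepoints else ["condition", "timepoint"]
        for key, sub in self.samples.groupby(cols, sort=True):
            yield key, list(sub.index)

    def copy(self) -> "PrecursorTable":
        return PrecursorTable(
            self.intensities.copy(), self.samples.copy(),
            self.annotations.copy(), self.is_log2,
        )


@dataclass
class SiteTable:
    """Per-unique-phosphosite intensities.

    Rows are (protein, residue, position) sites; ``sites`` records the
    residue annotation and provenance ("mono" for median-merged
    monophosphorylated evidence, "split-from-multi" for sites only seen
    on multiphosphorylated precursors).
    """

    intensities: pd.DataFrame  # rows = site ids "protein:S89"
    samples: pd.DataFrame
    sites: pd.DataFrame  # protein, residue, position, provenance
    is_log2: bool = True

    def __post_init__(self) -> None:
        _validate_samples(self.samples)
        dup = self.sites.duplicated(subset=["protein", "position"])
        if dup.any():
            raise ValueError("duplicate (protein, position) rows in site table")


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------


def log2_and_center(table: PrecursorTable) -> PrecursorTable:
    """Log2-transform (if linear) and mean-center each sample.

    Each sample's mean over its present values is shifted to the grand
    mean of all samples' means, so the operation is idempotent and
    preserves within-sample contrasts.  Missing entries stay missing.
    """
    out = table.copy()
    vals = out.intensities.to_numpy(dtype=float)
    if not out.is_log2:
        if np.nanmin(vals) <= 0:
            raise ValueError("linear intensities must be positive to log2")
        vals = np.log2(vals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_means = np.nanmean(vals, axis=0)
    if np.isnan(col_means).any():
        bad = out.intensities.columns[np.isnan(col_means)].tolist()
        raise ValueError(f"samples with zero present values: {bad}")
    vals = vals - col_means[None, :] + col_means.mean()
    out.intensities = pd.DataFrame(
        vals, index=out.intensities.index, columns=out.intensities.columns)
    out.is_log2 = True
    return out


def filter_by_replication(
    table: PrecursorTable,
    min_present: int = 2,
    pool_timepoints: bool = False,
) -> tuple[PrecursorTable, pd.DataFrame]:
    """Keep precursors observed in >= ``min_present`` replicates of at
    least one condition(-timepoint) triplicate.

    Returns the filtered table and a log of dropped precursors with the
    reason.  ``pool_timepoints`` evaluates the rule per condition pooling
    all timepoints instead of per condition x timepoint.
    """
    groups = list(table.triplicate_groups(pool_timepoints))
    for key, cols in groups:
        if len(cols) < min_present:
            raise ValueError(
                f"triplicate group {key} has only {len(cols)} samples")
    present = table.intensities.notna()
    keep = pd.Series(False, index=table.intensities.index)
    for _, cols in groups:
        keep |= present[cols].sum(axis=1) >= min_present
    dropped = pd.DataFrame(
        {"precursor_id": table.intensities.index[~keep],
         "reason": f"fewer than {min_present} replicates in every triplicate"})
    out = table.copy()
    out.intensities = out.intensities.loc[keep]
    out.annotations = out.annotations.loc[keep]
    return out, dropped


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


def _triplicate_sd(table: PrecursorTable) -> float:
    """Mean SD over all replicate triplicate series with >= 2 observations."""
    sds = []
    for _, cols in table.triplicate_groups():
        sub = table.intensities[cols]
        counts = sub.notna().sum(axis=1)
        sd = sub.std(axis=1, ddof=1)
        sds.append(sd[counts >= 2])
    allsd = pd.concat(sds).dropna()
    return float(allsd.mean()) if len(allsd) else 0.0


def impute_missing(
    table: PrecursorTable,
    seed: int,
    sigma: float | None = None,
) -> PrecursorTable:
    """Two-branch imputation at the precursor level.

    Per missing value, with the triplicate being its (condition,
    timepoint) replicate series:

    * branch A — the triplicate has >= 1 observation: draw from
      Normal(mean of the triplicate's present values, sigma);
    * branch B — the triplicate is fully missing: draw from
      Normal(precursor's minimum observed value - log2(3), sigma),
      i.e. centered threefold lower on the linear scale.

    ``sigma`` defaults to the mean within-triplicate SD over the whole
    table.  Present values are never overwritten; a fixed seed makes the
    imputed table reproducible.  Requires a log2-scale table.
    """
    if not table.is_log2:
        raise ValueError("impute_missing expects a log2-scale table")
    if sigma is None:
        sigma = _triplicate_sd(table)
    rng = np.random.default_rng(seed)
    out = table.copy()
    vals = out.intensities.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        row_min = np.nanmin(vals, axis=1)
    if np.isnan(row_min).any():
        bad = out.intensities.index[np.isnan(row_min)].tolist()[:5]
        raise ValueError(
            f"precursors with zero present values cannot be imputed: {bad}")
    col_of = {s: j for j, s in enumerate(out.intensities.columns)}
    for _, cols in table.triplicate_groups():
        jj = [col_of[c] for c in cols]
        block = vals[:, jj]
        missing = np.isnan(block)
        if not missing.any():
            continue
        with warnings.catch_warnings():
            # all-missing triplicates legitimately yield NaN means here
            warnings.simplefilter("ignore", RuntimeWarning)
            trip_mean = np.nanmean(np.where(missing, np.nan, block), axis=1)
        center = np.where(np.isnan(trip_mean), row_min - np.log2(3.0), trip_mean)
        draws = center[:, None] + rng.normal(0.0, 1.0, block.shape) * sigma
        vals[:, jj] = np.where(missing, draws, block)
    out.intensities = pd.DataFrame(
        vals, index=out.intensities.index, columns=out.intensities.columns)
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_protein(table: PrecursorTable) -> pd.DataFrame:
    """Sum precursor intensities to protein level (linear-scale sum,
    re-logged); returns a protein x sample log2 DataFrame."""
    prot = table.annotations.get("protein")
    if prot is None or prot.isna().any():
        bad = ([] if prot is None
               else table.annotations.index[prot.isna()].tolist()[:5])
        raise ValueError(f"precursors without protein annotation: {bad}")
    linear = np.power(2.0, table.intensities) if table.is_log2 else table.intensities
    summed = linear.groupby(prot).sum(min_count=1)
    return np.log2(summed)


def _parse_sites(site_str: str, precursor_id) -> list[tuple[str, int]]:
    parts = str(site_str).split("+")
    out = []
    for p in parts:
        m = SITE_RE.match(p.strip())
        if not m:
            raise ValueError(
                f"precursor {precursor_id!r}: malformed site {p!r} "
                "(expected e.g. 'S89' or 'S371+S374')")
        out.append((m.group(1), int(m.group(2))))
    return out


def deduplicate_precursors(table: PrecursorTable) -> PrecursorTable:
    """Resolve colliding precursors (same protein + site string + charge
    identity encoded in the id base) keeping high-confidence localization
    over low, then first-seen."""
    ann = table.annotations
    if "confidence" not in ann.columns:
        return table
    key = ann["protein"].astype(str) + "|" + ann["sites"].astype(str)
    rank = ann["confidence"].map({"high": 0, "low": 1}).fillna(2)
    order = pd.DataFrame({"key": key, "rank": rank,
                          "pos": range(len(ann))}, index=ann.index)
    keep_ids = (order.sort_values(["key", "rank", "pos"])
                .drop_duplicates("key").index)
    keep = table.intensities.index.isin(keep_ids)
    out = table.copy()
    out.intensities = out.intensities.loc[keep]
    out.annotations = out.annotations.loc[keep]
    return out


def merge_sites(table: PrecursorTable) -> SiteTable:
    """Collapse precursors to unique phosphosites.

    Monophosphorylated precursors mapping to the same (protein, position)
    are merged by per-sample median.  Multiphosphorylated precursors are
    split into their constituent sites and retained only for sites with
    no monophosphorylated evidence (provenance "split-from-multi").
    Conflicting residue letters at one position raise.
    """
    ann = table.annotations
    for col in ("protein", "sites"):
        if col not in ann.columns:
            raise ValueError(f"precursor annotations lack {col!r}")
    parsed = {pid: _parse_sites(ann.at[pid, "sites"], pid) for pid in ann.index}
    residue_at: dict[tuple[str, int], str] = {}
    for pid, sites in parsed.items():
        protein = ann.at[pid, "protein"]
        for res, pos in sites:
            prev = residue_at.setdefault((protein, pos), res)
            if prev != res:
                raise ValueError(
                    f"conflicting residues at {protein} position {pos}: "
                    f"{prev} vs {res}")
    mono_members: dict[tuple[str, int], list] = {}
    multi_members: dict[tuple[str, int], list] = {}
    for pid, sites in parsed.items():
        protein = ann.at[pid, "protein"]
        target = mono_members if len(sites) == 1 else multi_members
        for _, pos in sites:
            target.setdefault((protein, pos), []).append(pid)
    rows, meta = [], []
    for (protein, pos), pids in sorted(mono_members.items()):
        rows.append(table.intensities.loc[pids].median(axis=0))
        meta.append(dict(protein=protein, residue=residue_at[(protein, pos)],
                         position=pos, provenance="mono"))
    for (protein, pos), pids in sorted(multi_members.items()):
        if (protein, pos) in mono_members:
            continue
        rows.append(table.intensities.loc[pids].median(axis=0))
        meta.append(dict(protein=protein, residue=residue_at[(protein, pos)],
                         position=pos, provenance="split-from-multi"))
    sites_df = pd.DataFrame(meta)
    site_ids = sites_df["protein"] + ":" + sites_df["residue"] + \
        sites_df["position"].astype(str)
    intens = pd.DataFrame(rows)
    intens.index = site_ids
    sites_df.index = site_ids
    return SiteTable(intensities=intens, samples=table.samples.copy(),
                     sites=sites_df, is_log2=table.is_log2)


# ---------------------------------------------------------------------------
# moderated differential statistics
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior to
    observed sample variances (each with ``df`` residual degrees of
    freedom), on the log scale.

    Returns (prior_df, prior_var).  prior_df is inf when the observed
    log-variance spread is no larger than expected from sampling alone
    (complete shrinkage to a common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var > 0:
        prior_df = 2.0 * _trigamma_inverse(e_var)
        prior_var = float(
            np.exp(e_mean + digamma(prior_df / 2.0) - np.log(prior_df / 2.0)))
    else:
        prior_df = np.inf
        prior_var = float(np.mean(s2))
    return prior_df, prior_var


def differential_phospho(
    sites: SiteTable,
    window: tuple[float, ...] = DEFAULT_WINDOW,
    condition_active: str = "Cdc5",
    condition_control: str = "Cdc5KD",
    design: str = "paired",
    prior_df: float | None = None,
    candidate_alpha: float = CANDIDATE_ALPHA,
    screen_alpha: float = SCREEN_ALPHA,
) -> pd.DataFrame:
    """Kinase-active vs. kinase-dead differential phosphorylation.

    Per site, the log2 fold change is the mean over replicates and the
    post-induction timepoint window of the active-minus-control log2
    intensity (matched per replicate x timepoint under the paired
    design).  Site variances are shrunk toward an empirical-Bayes prior
    fitted by method of moments on log variances; the moderated t gains
    the prior degrees of freedom.  P-values are two-sided and
    Benjamini–Hochberg adjusted; ``candidate`` marks adjusted
    p <= ``candidate_alpha``, ``significant`` the ``screen_alpha`` screen.

    ``prior_df`` overrides the fitted prior: 0 disables shrinkage
    (ordinary paired t), inf forces complete shrinkage.
    """
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    samp = sites.samples
    window = tuple(float(w) for w in window)
    avail = set(samp["timepoint"].astype(float))
    if not set(window) <= avail:
        raise ValueError(f"window {window} not within available timepoints {sorted(avail)}")
    in_win = samp["timepoint"].astype(float).isin(window)
    active = samp[in_win & (samp["condition"] == condition_active)]
    control = samp[in_win & (samp["condition"] == condition_control)]
    if design == "paired":
        a_map = {(r, t): sid for sid, r, t in zip(
            active.index, active["replicate"], active["timepoint"])}
        c_map = {(r, t): sid for sid, r, t in zip(
            control.index, control["replicate"], control["timepoint"])}
        pairs = sorted(set(a_map) & set(c_map))
        if len(pairs) < 2:
            raise ValueError(
                f"only {len(pairs)} matched replicate/timepoint pairs; need >= 2")
        diffs = (sites.intensities[[a_map[p] for p in pairs]].to_numpy()
                 - sites.intensities[[c_map[p] for p in pairs]].to_numpy())
        if np.isnan(diffs).any():
            raise ValueError("missing values present; impute before testing")
        n = diffs.shape[1]
        log2fc = diffs.mean(axis=1)
        s2 = diffs.var(axis=1, ddof=1)
        se_unit = 1.0 / np.sqrt(n)
        df_resid = n - 1
    else:
        a_cols = list(active.index)
        c_cols = list(control.index)
        xa = sites.intensities[a_cols].to_numpy()
        xc = sites.intensities[c_cols].to_numpy()
        if np.isnan(xa).any() or np.isnan(xc).any():
            raise ValueError("missing values present; impute before testing")
        na, nc = xa.shape[1], xc.shape[1]
        if na < 2 or nc < 2:
            raise ValueError("need >= 2 samples per condition")
        log2fc = xa.mean(axis=1) - xc.mean(axis=1)
        s2 = ((xa.var(axis=1, ddof=1) * (na - 1)
               + xc.var(axis=1, ddof=1) * (nc - 1)) / (na + nc - 2))
        se_unit = np.sqrt(1.0 / na + 1.0 / nc)
        df_resid = na + nc - 2
    if prior_df is None:
        d0, s0 = fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0 = 0.0, 0.0
    elif np.isinf(prior_df):
        d0, s0 = np.inf, float(np.mean(s2))
    else:
        d0 = float(prior_df)
        _, s0 = fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    se = np.sqrt(s2_post) * se_unit
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    p[se == 0] = 1.0  # identical values in both conditions
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = sites.sites.copy()
    out["log2fc"] = log2fc
    out["t_moderated"] = t_mod
    out["p"] = p
    out["p_adjusted"] = p_adj
    out["candidate"] = p_adj <= candidate_alpha
    out["significant"] = p_adj <= screen_alpha
    out["prior_df"] = d0
    out["df_total"] = df_total
    return out


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_precursor_tsv(path, is_log2: bool = False) -> PrecursorTable:
    """Read a wide precursor TSV.

    Annotation columns: precursor_id, protein, sites, confidence; every
    remaining column is a sample named ``<condition>_r<replicate>_t<tp>``
    (e.g. ``Cdc5_r1_t2``).  A column that fits neither schema is a
    schema error.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["precursor_id", "protein", "sites"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"precursor TSV lacks required columns: {missing}")
    ann_cols = [c for c in ("protein", "sites", "confidence") if c in df.columns]
    sample_cols, meta = [], []
    for c in df.columns:
        if c in ann_cols or c == "precursor_id":
            continue
        m = SAMPLE_RE.match(c)
        if not m:
            raise ValueError(
                f"column {c!r} is neither an annotation nor a sample "
                "(expected '<condition>_r<rep>_t<tp>')")
        sample_cols.append(c)
        meta.append(dict(sample_id=c, condition=m["condition"],
                         replicate=int(m["replicate"]), timepoint=float(m["tp"])))
    if not sample_cols:
        raise ValueError("no sample columns found")
    df = df.set_index("precursor_id")
    samples = pd.DataFrame(meta).set_index("sample_id")
    return PrecursorTable(
        intensities=df[sample_cols].astype(float),
        samples=samples,
        annotations=df[ann_cols],
        is_log2=is_log2,
    )


def write_precursor_tsv(table: PrecursorTable, path) -> None:
    wide = pd.concat([table.annotations, table.intensities], axis=1)
    wide.index.name = "precursor_id"
    wide.to_csv(path, sep="\t", float_format="%.6g")
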