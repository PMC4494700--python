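"""Presence/absence genotyping from specific read counts.

For each amplicon, log10 specific read counts across samples are modelled
as a 1- or 2-component univariate Gaussian mixture with unequal variances,
fitted by MAP-EM with conjugate priors: component means are shrunk toward
the grand mean with weight ``prior_shrinkage`` and variances carry an
inverse-gamma-type prior with scale ``prior_scale`` (which prevents the
degenerate zero-variance solutions that plague unpenalized mixtures of
near-constant count data).  The number of components is selected by BIC,
ties broken toward one component.

Two post-hoc rules override pathological fits (both disabled in
``prior_only`` mode, which relies on the variance prior instead):

* Rule A — if every sample has fewer than ``min_reads_all_absent`` (10)
  specific reads, the amplicon is absent in all samples.
* Rule B — if the two component means are closer than
  ``cluster_merge_distance`` (0.5 log10 units), refit with one component.

In a 2-component fit the higher-mean component means "amplicon present";
each sample's genotyping quality is the log10 odds of its assigned versus
alternative component posterior.  Passed E amplicons are finally checked
for short-insertion read-through: samples whose specific reads carry the
family motif at > ``motif_fraction_threshold`` are flipped to absent.

E and G presence calls combine into diallelic genotypes:
(E present, G absent) -> 0/0, (E present, G present) -> 0/1,
(E absent, G present) -> 1/1, (E absent, G absent) -> no call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .panel import Panel
from .tagmap import AmpliconCountRecord

PRIOR_DOF = 3.0  # variance-prior degrees of freedom (univariate d + 2)

PRESENT = "present"
ABSENT = "absent"
NO_CALL = "no_call"

STATUS_OK = "ok"
STATUS_FORCED_SINGLE = "forced_single"
STATUS_FORCED_ALL_ABSENT = "forced_all_absent"
STATUS_FAILED = "failed"


def log_transform(counts) -> np.ndarray:
    """log10 of read counts with zeros mapped to 0.0 (i.e. counts of 0 set to 1)."""
    arr = np.asarray(counts)
    if arr.size and not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("counts must be integers")
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    out = np.zeros(arr.shape, dtype=float)
    nz = arr > 0
    out[nz] = np.log10(arr[nz])
    return out


@dataclass
class ClusterFit:
    """A fitted 1- or 2-component mixture on log10 counts for one amplicon."""

    locus_id: str
    reaction: str
    n_components: int
    means: np.ndarray          # ordered (low, high) when 2 components
    sds: np.ndarray
    weights: np.ndarray
    posteriors: np.ndarray     # (n_samples, n_components), rows sum to 1
    assigned: np.ndarray       # component index per sample
    log_likelihood: float
    bic: dict
    fit_status: str
    n_iter: int
    converged: bool
    logcounts: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.logcounts)


class ReadCountMixture:
    """MAP-EM univariate Gaussian mixture model for one amplicon's log10 counts.

    Parameters
    ----------
    logcounts : array-like
        log10 specific read counts, one value per sample (>= 3 samples).
    config : PipelineConfig, optional
        Supplies ``prior_shrinkage``, ``prior_scale`` and EM controls.

    Examples
    --------
    >>> res = ReadCountMixture([0.0, 0.3, 0.0, 4.0, 4.1, 3.9]).fit()
    >>> res.n_components
    2
    """

    def __init__(self, logcounts, config: PipelineConfig | None = None):
        self.endog = np.asarray(logcounts, dtype=float)
        if self.endog.ndim != 1 or self.endog.size < 3:
            raise ValueError("need a 1-D vector of >= 3 log counts")
        self.config = config or PipelineConfig()
        self.prior_mean = float(np.mean(self.endog))
        self.kappa = self.config.prior_shrinkage
        self.zeta = self.config.prior_scale
        self.nu = PRIOR_DOF

    # --- MAP estimation -------------------------------------------------

    def _map_variance(self, n_k: float, ss_k: float) -> float:
        """Posterior-mode variance under the inverse-gamma prior.

        The prior is decoupled from the component mean: a tiny cluster far
        from the grand mean gets the prior-mode variance ``zeta/(nu+3)``
        rather than one inflated by its distance, so legitimate singleton
        clusters keep a small, well-regularized spread.
        """
        return (self.zeta + ss_k) / (self.nu + n_k + 3.0)

    def _fit_single(self) -> dict:
        x = self.endog
        n = x.size
        xbar = float(np.mean(x))
        mu = (n * xbar + self.kappa * self.prior_mean) / (n + self.kappa)
        var = self._map_variance(n, float(np.sum((x - xbar) ** 2)))
        sd = math.sqrt(var)
        ll = float(np.sum(_norm_logpdf(x, mu, sd)))
        return {
            "n_components": 1,
            "means": np.array([mu]),
            "sds": np.array([sd]),
            "weights": np.array([1.0]),
            "posteriors": np.ones((n, 1)),
            "log_likelihood": ll,
            "n_iter": 0,
            "converged": True,
        }

    def _fit_pair(self) -> dict | None:
        """Deterministically initialized MAP-EM for 2 components; None if degenerate.

        EM is run from the 25th/75th-percentile init and from every split
        of the sorted data (two-moment init per side); the best converged
        likelihood wins.  For univariate data this candidate set covers
        every partition a restarted EM could refine, so the result is both
        deterministic and restart-robust.
        """
        x = self.endog
        n = x.size
        if float(np.ptp(x)) < 1e-12:
            return None  # no variability at all
        sd0 = max(float(np.std(x)), math.sqrt(self.zeta / (self.nu + 2.0)))
        inits: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        m_lo, m_hi = np.percentile(x, [25.0, 75.0])
        if m_hi - m_lo < 1e-12:
            m_lo, m_hi = float(np.min(x)), float(np.max(x))
        inits.append(
            (np.array([m_lo, m_hi], float), np.array([sd0, sd0]), np.array([0.5, 0.5]))
        )
        xs = np.sort(x)
        if n <= 100:
            split_points = range(1, n)
        else:  # quantile-spaced subset keeps the candidate set bounded
            split_points = sorted({int(q) for q in np.linspace(1, n - 1, 64)})
        for k in split_points:
            lo, hi = xs[:k], xs[k:]
            if hi.mean() - lo.mean() < 1e-12:
                continue
            sds = np.array(
                [
                    max(float(lo.std()), 0.05),
                    max(float(hi.std()), 0.05),
                ]
            )
            inits.append(
                (np.array([lo.mean(), hi.mean()]), sds, np.array([k / n, 1 - k / n]))
            )
        best: dict | None = None
        for means, sds, weights in inits:
            fit = self._em(means.copy(), sds.copy(), weights.copy())
            if best is None or fit["log_likelihood"] > best["log_likelihood"] + 1e-12:
                best = fit
        return best

    def _em(self, means: np.ndarray, sds: np.ndarray, weights: np.ndarray) -> dict:
        x = self.endog
        n = x.size
        ll_prev = -np.inf
        n_iter = 0
        converged = False
        resp = np.empty((n, 2))
        for n_iter in range(1, self.config.em_max_iter + 1):
            # E step
            logp = np.log(weights)[None, :] + _norm_logpdf(
                x[:, None], means[None, :], sds[None, :]
            )
            m = logp.max(axis=1, keepdims=True)
            lse = m[:, 0] + np.log(np.sum(np.exp(logp - m), axis=1))
            resp = np.exp(logp - lse[:, None])
            ll = float(np.sum(lse))
            if abs(ll - ll_prev) < self.config.em_tol:
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
            # M step (MAP)
            n_k = resp.sum(axis=0)
            n_k = np.maximum(n_k, 1e-12)
            xbar = (resp * x[:, None]).sum(axis=0) / n_k
            means = (n_k * xbar + self.kappa * self.prior_mean) / (n_k + self.kappa)
            ss = (resp * (x[:, None] - xbar[None, :]) ** 2).sum(axis=0)
            var = np.array([self._map_variance(n_k[k], ss[k]) for k in range(2)])
            sds = np.sqrt(var)
            weights = n_k / n
        order = np.argsort(means)
        return {
            "n_components": 2,
            "means": means[order],
            "sds": sds[order],
            "weights": weights[order],
            "posteriors": resp[:, order],
            "log_likelihood": ll_prev,
            "n_iter": n_iter,
            "converged": converged,
        }

    def fit(self, n_components: int | None = None) -> "ReadCountMixtureResults":
        """Fit; when ``n_components`` is None, select 1 vs 2 by BIC (ties -> 1)."""
        n = self.endog.size
        single = self._fit_single()
        status = STATUS_OK
        if n_components == 1:
            chosen = single
            pair = None
        else:
            pair = self._fit_pair()
            if pair is None:
                chosen = single
                status = STATUS_FORCED_SINGLE if n_components == 2 else STATUS_OK
                if np.ptp(self.endog) < 1e-12 and n_components is None:
                    status = STATUS_FORCED_SINGLE
            elif n_components == 2:
                chosen = pair
            else:
                bic1 = 2.0 * single["log_likelihood"] - 2.0 * math.log(n)
                bic2 = 2.0 * pair["log_likelihood"] - 5.0 * math.log(n)
                chosen = pair if bic2 > bic1 else single
        bic = {
            1: 2.0 * single["log_likelihood"] - 2.0 * math.log(n),
            2: (2.0 * pair["log_likelihood"] - 5.0 * math.log(n)) if pair else None,
        }
        return ReadCountMixtureResults(self, chosen, status, bic)


def _norm_logpdf(x, mu, sd):
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


class ReadCountMixtureResults:
    """Results of a :class:`ReadCountMixture` fit."""

    def __init__(self, model: ReadCountMixture, params: dict, fit_status: str, bic: dict):
        self.model = model
        self.fit_status = fit_status
        self.bic = bic
        self.n_components = params["n_components"]
        self.means = params["means"]
        self.sds = params["sds"]
        self.weights = params["weights"]
        self.posteriors = params["posteriors"]
        self.log_likelihood = params["log_likelihood"]
        self.n_iter = params["n_iter"]
        self.converged = params["converged"]

    @property
    def assigned(self) -> np.ndarray:
        return np.argmax(self.posteriors, axis=1)

    def summary(self) -> str:
        lines = [
            "Read-count Gaussian mixture (MAP-EM)",
            f"  n samples:      {self.model.endog.size}",
            f"  components:     {self.n_components}",
            f"  log-likelihood: {self.log_likelihood:.4f}",
            f"  BIC(1)={self.bic[1]:.2f}"
            + (f"  BIC(2)={self.bic[2]:.2f}" if self.bic[2] is not None else ""),
            f"  status:         {self.fit_status}",
            "  comp      mean        sd    weight",
        ]
        for k in range(self.n_components):
            lines.append(
                f"  {k:4d}  {self.means[k]:8.4f}  {self.sds[k]:8.4f}  {self.weights[k]:8.4f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Histogram of log10 counts with fitted component densities."""
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        x = self.model.endog
        ax.hist(x, bins=max(10, x.size // 2), density=True, alpha=0.4, color="grey")
        grid = np.linspace(x.min() - 0.5, x.max() + 0.5, 400)
        for k in range(self.n_components):
            dens = self.weights[k] * np.exp(
                _norm_logpdf(grid, self.means[k], self.sds[k])
            )
            ax.plot(grid, dens, label=f"component {k} (mean {self.means[k]:.2f})")
        ax.set_xlabel("log10 specific read count")
        ax.set_ylabel("density")
        ax.legend()
        return ax

    def to_cluster_fit(self, locus_id: str = "", reaction: str = "") -> ClusterFit:
        return ClusterFit(
            locus_id=locus_id,
            reaction=reaction,
            n_components=self.n_components,
            means=self.means.copy(),
            sds=self.sds.copy(),
            weights=self.weights.copy(),
            posteriors=self.posteriors.copy(),
            assigned=self.assigned.copy(),
            log_likelihood=self.log_likelihood,
            bic=dict(self.bic),
            fit_status=self.fit_status,
            n_iter=self.n_iter,
            converged=self.converged,
            logcounts=self.model.endog.copy(),
        )


def fit_clusters(
    logcounts,
    config: PipelineConfig | None = None,
    locus_id: str = "",
    reaction: str = "",
) -> ClusterFit:
    """Fit the per-amplicon mixture (model selection by BIC) and package the result."""
    config = config or PipelineConfig()
    return ReadCountMixture(logcounts, config).fit().to_cluster_fit(locus_id, reaction)


def apply_post_hoc_rules(fit: ClusterFit, counts, config: PipelineConfig | None = None) -> ClusterFit:
    """Apply rule A (<10 reads everywhere -> all absent) and rule B (merge close clusters).

    Returns a new ClusterFit; no-op in ``prior_only`` mode.
    """
    config = config or PipelineConfig()
    if config.prior_only:
        return fit
    counts = np.asarray(counts)
    if np.all(counts < config.min_reads_all_absent):
        return replace(fit, fit_status=STATUS_FORCED_ALL_ABSENT)
    if fit.n_components == 2 and (fit.means[1] - fit.means[0]) < config.cluster_merge_distance:
        refit = (
            ReadCountMixture(fit.logcounts, config)
            .fit(n_components=1)
            .to_cluster_fit(fit.locus_id, fit.reaction)
        )
        return replace(refit, fit_status=STATUS_FORCED_SINGLE)
    return fit


@dataclass
class ReactionCallSet:
    """Presence/absence calls with quality scores for one amplicon across samples."""

    locus_id: str
    reaction: str
    sample_ids: list[str]
    calls: list[str]
    quality: np.ndarray
    low_quality: np.ndarray
    override: np.ndarray
    fit_status: str

    def call_array(self) -> np.ndarray:
        return np.array(self.calls)


def label_and_call(
    fit: ClusterFit,
    config: PipelineConfig | None = None,
    sample_ids: list[str] | None = None,
) -> ReactionCallSet:
    """Turn a cluster fit into per-sample presence/absence calls with quality scores.

    Two components: the higher-mean component means amplicon present;
    quality is the log10 posterior odds, capped at ``quality_cap``.  One
    component: all present iff the component mean >= ``qc_high_mean_min``
    (an all-absent amplicon is normally captured by rule A first); quality
    is the cap.  ``forced_all_absent``: all absent at the cap.
    """
    config = config or PipelineConfig()
    if fit.fit_status == STATUS_FAILED:
        raise ValueError("cannot call genotypes from a failed fit")
    n = fit.n_samples
    ids = sample_ids if sample_ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise ValueError("sample_ids length mismatch")
    cap = config.quality_cap

    if fit.fit_status == STATUS_FORCED_ALL_ABSENT:
        calls = [ABSENT] * n
        quality = np.full(n, cap)
    elif fit.n_components == 2:
        assigned = fit.assigned
        p_assigned = fit.posteriors[np.arange(n), assigned]
        p_other = fit.posteriors[np.arange(n), 1 - assigned]
        with np.errstate(divide="ignore"):
            quality = np.log10(p_assigned) - np.log10(p_other)
        quality = np.minimum(np.nan_to_num(quality, posinf=cap), cap)
        calls = [PRESENT if a == 1 else ABSENT for a in assigned]
    else:
        present = fit.means[0] >= config.qc_high_mean_min
        calls = [PRESENT if present else ABSENT] * n
        quality = np.full(n, cap)
    return ReactionCallSet(
        locus_id=fit.locus_id,
        reaction=fit.reaction,
        sample_ids=list(ids),
        calls=calls,
        quality=quality,
        low_quality=quality < config.quality_flag_threshold,
        override=np.zeros(n, dtype=bool),
        fit_status=fit.fit_status,
    )


def apply_short_insertion_override(
    callset: ReactionCallSet,
    motif_fractions,
    config: PipelineConfig | None = None,
) -> ReactionCallSet:
    """Flip E calls to absent where the motif fraction exceeds the threshold (strictly).

    High numbers of motif-bearing specific reads diagnose read-through
    across a short truncated element: the amplicon is "absent" in the
    diallelic sense (the insertion IS present).  E reactions only.
    """
    config = config or PipelineConfig()
    if callset.reaction != "E":
        raise ValueError("short-insertion override applies to E reactions only")
    fractions = np.asarray(motif_fractions, dtype=float)
    if fractions.shape != (len(callset.sample_ids),):
        raise ValueError("motif_fractions must align with sample_ids")
    flip = fractions > config.motif_fraction_threshold
    calls = [ABSENT if f else c for c, f in zip(callset.calls, flip)]
    return replace(callset, calls=calls, override=callset.override | flip)


@dataclass
class AmpliconQCResult:
    locus_id: str
    reaction: str
    passed: bool
    reasons: list[str]


def qc_amplicon(
    fit: ClusterFit,
    records: list[AmpliconCountRecord],
    config: PipelineConfig | None = None,
) -> AmpliconQCResult:
    """Cluster-statistics and tag-uniqueness quality control for one amplicon.

    Fails when: the low cluster mean exceeds ``qc_low_mean_max``; the high
    cluster mean falls below ``qc_high_mean_min``; any component sd exceeds
    ``qc_sd_max``; or more than ``qc_sample_frac_max`` of samples each have
    under ``qc_unique_frac_min`` of tags uniquely aligned.  A
    forced-all-absent amplicon skips the cluster checks (validly absent
    everywhere).
    """
    config = config or PipelineConfig()
    reasons: list[str] = []
    if fit.fit_status == STATUS_FAILED:
        reasons.append("fit_failed")
    elif fit.fit_status != STATUS_FORCED_ALL_ABSENT:
        if fit.n_components == 2:
            if fit.means[0] > config.qc_low_mean_max:
                reasons.append("low_cluster_mean_high")
            if fit.means[1] < config.qc_high_mean_min:
                reasons.append("high_cluster_mean_low")
        if np.any(fit.sds > config.qc_sd_max):
            reasons.append("sd_excess")
    # Uniqueness rule over samples that actually have tags: a sample with
    # no reads at an absent amplicon says nothing about tag specificity.
    with_tags = [r for r in records if r.n_tags > 0]
    if with_tags:
        n_low = sum(r.unique_fraction < config.qc_unique_frac_min for r in with_tags)
        if n_low / len(with_tags) > config.qc_sample_frac_max:
            reasons.append("nonunique_tags")
    return AmpliconQCResult(
        locus_id=fit.locus_id,
        reaction=fit.reaction,
        passed=not reasons,
        reasons=reasons,
    )


GENOTYPE_TABLE = {
    (PRESENT, ABSENT): "0/0",
    (PRESENT, PRESENT): "0/1",
    (ABSENT, PRESENT): "1/1",
    (ABSENT, ABSENT): "./.",
}


@dataclass
class AllelicGenotype:
    sample_id: str
    locus_id: str
    genotype: str  # '0/0', '0/1', '1/1' or './.'
    quality: float
    e_call: str
    g_call: str
    e_quality: float
    g_quality: float
    e_override: bool


def combine_calls(
    e_calls: ReactionCallSet,
    g_calls: ReactionCallSet,
    e_qc: AmpliconQCResult | None = None,
    g_qc: AmpliconQCResult | None = None,
) -> list[AllelicGenotype]:
    """Combine E and G presence calls into diallelic genotypes.

    Exactly the four-row truth table: (present, absent) -> 0/0,
    (present, present) -> 0/1, (absent, present) -> 1/1,
    (absent, absent) -> no call.  Combined quality is the minimum of the
    two reaction qualities.  Raises unless both reactions passed QC and
    cover identical samples.
    """
    if e_calls.sample_ids != g_calls.sample_ids:
        raise ValueError("E and G call sets cover different samples")
    for qc in (e_qc, g_qc):
        if qc is not None and not qc.passed:
            raise ValueError(
                f"cannot combine calls for {qc.locus_id}/{qc.reaction}: QC failed ({qc.reasons})"
            )
    out = []
    for i, sid in enumerate(e_calls.sample_ids):
        gt = GENOTYPE_TABLE[(e_calls.calls[i], g_calls.calls[i])]
        out.append(
            AllelicGenotype(
                sample_id=sid,
                locus_id=e_calls.locus_id,
                genotype=gt,
                quality=float(min(e_calls.quality[i], g_calls.quality[i])),
                e_call=e_calls.calls[i],
                g_call=g_calls.calls[i],
                e_quality=float(e_calls.quality[i]),
                g_quality=float(g_calls.quality[i]),
                e_override=bool(e_calls.override[i]),
            )
        )
    return out


def write_genotypes(
    calls: list[AllelicGenotype],
    panel: Panel,
    sample_ids: list[str],
    counts: dict | None,
    outdir: str | Path,
) -> None:
    """Write the combined genotypes as VCF 4.2 (symbolic <INS:ME>) and TSV.

    One VCF record per locus with combined calls; POS anchors at the last
    confidently empty-site base (E tag target end, converted to 1-based).
    ``counts`` optionally maps (sample, locus, reaction) -> specific count
    for the FORMAT fields.
    """
    import pysam

    outdir = Path(outdir)
    by_locus: dict[str, dict[str, AllelicGenotype]] = {}
    for c in calls:
        by_locus.setdefault(c.locus_id, {})[c.sample_id] = c

    header = pysam.VariantHeader()
    header.add_line("##source=retrocall")
    contigs = {}
    for loc in panel.loci:
        contigs.setdefault(loc.chrom, 0)
        contigs[loc.chrom] = max(contigs[loc.chrom], loc.e_tag_target.end + 1000)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.add_line('##ALT=<ID=INS:ME,Description="Mobile element insertion">')
    header.add_line('##INFO=<ID=TEFAM,Number=1,Type=String,Description="TE family">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=CQ,Number=1,Type=Float,Description="Combined genotyping quality (log10 odds)">')
    header.add_line('##FORMAT=<ID=ERC,Number=1,Type=Integer,Description="E-reaction specific read count">')
    header.add_line('##FORMAT=<ID=GRC,Number=1,Type=Integer,Description="G-reaction specific read count">')
    for sid in sample_ids:
        header.add_sample(sid)

    gt_map = {"0/0": (0, 0), "0/1": (0, 1), "1/1": (1, 1), "./.": (None, None)}
    with pysam.VariantFile(str(outdir / "genotypes.vcf"), "w", header=header) as vcf:
        for loc in panel.loci:
            if loc.locus_id not in by_locus:
                continue
            per_sample = by_locus[loc.locus_id]
            rec = vcf.new_record(
                contig=loc.chrom,
                start=loc.e_tag_target.end,
                stop=loc.e_tag_target.end + 1,
                alleles=("N", "<INS:ME>"),
                id=loc.locus_id,
            )
            rec.info["TEFAM"] = loc.te_family
            for sid in sample_ids:
                call = per_sample.get(sid)
                gt = gt_map[call.genotype if call else "./."]
                rec.samples[sid]["GT"] = gt
                if call:
                    rec.samples[sid]["CQ"] = call.quality
                    if counts:
                        rec.samples[sid]["ERC"] = int(counts.get((sid, loc.locus_id, "E"), 0))
                        rec.samples[sid]["GRC"] = int(counts.get((sid, loc.locus_id, "G"), 0))
            vcf.write(rec)

    rows = [
        {
            "sample_id": c.sample_id,
            "locus_id": c.locus_id,
            "genotype": c.genotype,
            "quality": round(c.quality, 4),
            "e_call": c.e_call,
            "g_call": c.g_call,
            "e_quality": round(c.e_quality, 4),
            "g_quality": round(c.g_quality, 4),
            "e_override": int(c.e_override),
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
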