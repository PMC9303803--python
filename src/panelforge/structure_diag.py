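"""Population-structure and ascertainment-bias diagnostics.

PCA follows the conventional genotype-matrix recipe: missing dosages
are replaced by the locus mean dosage 2p (which leaves the column mean
unchanged), columns are centered and scaled to unit variance, and
scores come from an SVD with a fixed sign convention so runs are
reproducible.  The ascertainment diagnostics compare observed folded
spectra against a reference (another spectrum or the neutral
expectation) class by class; they describe the distortion, they do not
make a decision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MISSING, SFS, GenotypeMatrix, ValidationError
from .popgen_stats import hw_exact_test_many

__all__ = [
    "PCAResult",
    "pca_genotypes",
    "ascertainment_compare",
    "hw_qq_data",
    "panel_separation_test",
    "hw_ternary_coords",
]


@dataclass
class PCAResult:
    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (n_loci_used, n_components)
    loci_used: list[str]
    imputed_fraction: float

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


def pca_genotypes(
    matrix: GenotypeMatrix,
    loci: list[str] | None = None,
    n_components: int = 10,
) -> PCAResult:
    """PCA of the dosage matrix with mean-dosage imputation.

    Zero-variance columns after imputation (monomorphic loci) cannot be
    unit-scaled and are dropped with a warning.  Component signs are
    fixed so the largest-magnitude loading of each component is
    positive.
    """
    if loci is not None:
        matrix = matrix.subset_loci(loci)
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs at least two samples")
    X = matrix.calls.astype(float)
    miss = X == MISSING
    X[miss] = np.nan
    col_mean = np.nanmean(X, axis=0)
    all_missing = np.isnan(col_mean)
    imputed_fraction = float(miss[:, ~all_missing].mean()) if (~all_missing).any() else 0.0
    inds = np.where(miss)
    X[inds] = np.take(np.nan_to_num(col_mean), inds[1])
    sd = X.std(axis=0)
    usable = (sd > 0) & ~all_missing
    if not usable.any():
        raise ValidationError("no polymorphic loci left for PCA")
    n_dropped = int((~usable).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-variance loci before scaling")
    Xs = (X[:, usable] - X[:, usable].mean(axis=0)) / sd[usable]
    k = min(n_components, min(Xs.shape) - 1) or 1
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U[:, :k] * S[:k]
    var = S**2 / (Xs.shape[0] - 1)
    evr = var[:k] / var.sum()
    return PCAResult(
        sample_ids=list(matrix.sample_ids),
        scores=scores,
        explained_variance_ratio=evr,
        loadings=Vt[:k].T,
        loci_used=[l for l, u in zip(matrix.locus_ids, usable) if u],
        imputed_fraction=imputed_fraction,
    )


def ascertainment_compare(
    observed: SFS, reference: SFS | np.ndarray
) -> tuple[pd.DataFrame, dict]:
    """Class-wise observed/reference ratios for two folded spectra.

    ``reference`` is either a second SFS at the same chromosome count
    (project first otherwise) or an expected-proportions vector.
    Ratios below 1 in the rare classes are the signature of
    MAF-threshold ascertainment.  Per-class Clopper-Pearson intervals
    on the observed proportions and a chi-square summary are returned;
    no accept/reject decision is made.
    """
    if isinstance(reference, SFS):
        if reference.n_chromosomes != observed.n_chromosomes:
            raise ValidationError(
                "chromosome counts differ; project one spectrum first"
            )
        ref_props = reference.proportions()
    else:
        ref_props = np.asarray(reference, dtype=float)
        if len(ref_props) != len(observed.folded_counts):
            raise ValidationError("reference class count mismatch")
        ref_props = ref_props / ref_props.sum()
    obs = observed.folded_counts
    total = obs.sum()
    obs_props = obs / total
    lo, hi = [], []
    for count in obs:
        ci = stats.beta.ppf([0.025, 0.975], [count, count + 1], [total - count + 1, total - count])
        lo.append(0.0 if count == 0 else ci[0])
        hi.append(1.0 if count == total else ci[1])
    table = pd.DataFrame(
        {
            "minor_allele_count": np.arange(1, len(obs) + 1),
            "observed_prop": obs_props,
            "reference_prop": ref_props,
            "ratio": np.where(ref_props > 0, obs_props / np.maximum(ref_props, 1e-300), np.inf),
            "ratio_ci_low": np.array(lo) / np.maximum(ref_props, 1e-300),
            "ratio_ci_high": np.array(hi) / np.maximum(ref_props, 1e-300),
        }
    )
    expected = ref_props * total
    keep = expected > 0
    chi2, p = stats.chisquare(obs[keep], expected[keep] * obs[keep].sum() / expected[keep].sum())
    summary = {"chi2": float(chi2), "p_value": float(p), "df": int(keep.sum() - 1)}
    return table, summary


def hw_qq_data(
    genotype_counts: np.ndarray,
    n_null_draws: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed-vs-null quantiles for HW exact-test p-values.

    ``genotype_counts`` is (n_loci, 3) hom/het/hom counts.  The null is
    generated by redrawing genotypes under HWE at each locus's
    estimated allele frequency and sample size, re-testing, and pooling
    ``n_null_draws`` replicates; the envelope spans the per-rank range
    of the null replicates.  Loci under paralog collapse push the upper
    tail of the observed quantiles off the diagonal.
    """
    counts = np.asarray(genotype_counts, dtype=np.int64)
    if counts.ndim != 2 or counts.shape[1] != 3 or len(counts) == 0:
        raise ValidationError("genotype_counts must be a non-empty (n_loci, 3) array")
    rng = np.random.default_rng(seed)
    n = counts.sum(axis=1)
    p_alt = (2 * counts[:, 2] + counts[:, 1]) / (2 * n)
    observed = np.sort(hw_exact_test_many(counts[:, 0], counts[:, 1], counts[:, 2]))
    null_sorted = np.empty((n_null_draws, len(counts)))
    probs = np.stack([(1 - p_alt) ** 2, 2 * p_alt * (1 - p_alt), p_alt**2], axis=1)
    for r in range(n_null_draws):
        sim = np.stack(
            [rng.multinomial(n_i, pr) for n_i, pr in zip(n, probs)], axis=0
        )
        null_sorted[r] = np.sort(
            hw_exact_test_many(sim[:, 0], sim[:, 1], sim[:, 2])
        )
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(counts) + 1),
            "observed_p": observed,
            "null_mean": null_sorted.mean(axis=0),
            "null_low": null_sorted.min(axis=0),
            "null_high": null_sorted.max(axis=0),
        }
    )


def panel_separation_test(
    result: PCAResult,
    panel_ids: list[str],
    n_permutations: int = 999,
    seed: int = 0,
    n_components: int = 2,
) -> tuple[float, float]:
    """Permutation test for discovery-panel separation in PCA space.

    Small discovery panels ascertain loci where the panel members
    themselves carry minor alleles, so each member becomes extreme
    along its own principal axis rather than the panel clustering
    together.  The test statistic is therefore the mean score *norm*
    (distance from the origin) of panel members minus that of
    non-members over the leading components; the p-value comes from
    permuting the membership labels.
    """
    if not panel_ids:
        raise ValidationError("empty panel")
    panel = set(panel_ids)
    is_panel = np.array([s in panel for s in result.sample_ids])
    if not is_panel.any() or is_panel.all():
        raise ValidationError("panel must be a proper subset of the scored samples")
    X = result.scores[:, :n_components]
    norm = np.linalg.norm(X, axis=1)
    stat = norm[is_panel].mean() - norm[~is_panel].mean()
    rng = np.random.default_rng(seed)
    exceed = sum(
        (lambda p: norm[p].mean() - norm[~p].mean())(rng.permutation(is_panel)) >= stat
        for _ in range(n_permutations)
    )
    return float(stat), (1 + exceed) / (n_permutations + 1)


def hw_ternary_coords(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float, float]:
    """Genotype fractions (f_AA, f_Aa, f_aa) for ternary plotting."""
    total = n_AA + n_Aa + n_aa
    if total <= 0:
        raise ValidationError("genotype counts sum to zero")
    return (n_AA / total, n_Aa / total, n_aa / total)
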