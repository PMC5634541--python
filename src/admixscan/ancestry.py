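"""Local- and global-ancestry estimation from phased haplotypes.

Local ancestry is inferred per haplotype with a windowed K-state HMM: within
a window of consecutive SNPs each ancestry's emission likelihood is the
product of Bernoulli likelihoods of the observed alleles under that
ancestry's panel frequencies; between adjacent windows ancestry switches at
a rate of ``switch_rate`` per Morgan (stay probability exp(-rate*d) plus a
uniform re-draw).  Posteriors come from the forward-backward recursion and
every SNP inherits its window's posterior.  Diploid local-ancestry
proportions are means over the two haplotypes, optionally averaged over
several phase configurations; global ancestry is the genome-wide mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, MISSING


@dataclass
class HmmParams:
    """Window size in SNPs, ancestry-switch rate per Morgan (defaults to the
    admixture age in generations), and a floor on per-SNP emission
    probabilities guarding against near-fixed panel frequencies."""

    window_snps: int = 50
    switch_rate: float = 8.0
    emission_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be positive")


@dataclass
class LocalAncestryField:
    """Per-individual, per-SNP ancestry proportions (n, m, k); rows over k
    sum to 1.  Houses the L_AFR / L_NAM regressors of the scan."""

    values: np.ndarray
    sample_ids: list[str]
    snps: pd.DataFrame
    ancestry_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 3:
            raise ValueError("values must be (n_samples, n_snps, k)")
        if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
            raise ValueError("ancestry proportions outside [0, 1]")
        if not np.allclose(v.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("ancestry proportions must sum to 1 over k")

    def to_long_frame(self) -> pd.DataFrame:
        n, m, k = self.values.shape
        recs = {
            "sample_id": np.repeat(self.sample_ids, m * k),
            "chrom": np.tile(np.repeat(self.snps["chrom"].to_numpy(), k), n),
            "bp": np.tile(np.repeat(self.snps["bp"].to_numpy(), k), n),
            "ancestry": np.tile(list(self.ancestry_labels), n * m),
            "proportion": self.values.ravel(),
        }
        return pd.DataFrame(recs)


@dataclass
class GlobalAncestry:
    """Per-individual genome-average ancestry proportions (n, k); houses the
    G_AFR / G_NAM regressors."""

    values: np.ndarray
    sample_ids: list[str]
    ancestry_labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=list(self.ancestry_labels))


def _window_bounds(m: int, w: int) -> np.ndarray:
    """Window start offsets for m SNPs at width w (last window truncated)."""
    return np.arange(0, m, w)


def infer_local_ancestry(
    haps: np.ndarray,
    freqs: np.ndarray,
    params: HmmParams,
    snps: pd.DataFrame,
) -> np.ndarray:
    """Posterior ancestry per haplotype: (H, m, k) from haplotypes (H, m),
    panel frequencies (k, m) and a SNP map with ``chrom`` and ``cm`` columns.

    Chromosomes are independent HMM chains; genetic distances between window
    midpoints set the switch kernel.
    """
    haps = np.asarray(haps)
    if not np.isin(haps, [0, 1]).all():
        raise ValueError("haplotype entries must be 0/1")
    freqs = np.asarray(freqs, dtype=float)
    H, m = haps.shape
    k = freqs.shape[0]
    if freqs.shape[1] != m or len(snps) != m:
        raise ValueError("freqs/snp map do not match haplotype width")
    if k == 1:
        return np.ones((H, m, 1))

    f = np.clip(freqs, params.emission_floor, 1.0 - params.emission_floor)
    # per-SNP log-likelihood under each ancestry: (H, m, k)
    logf, log1mf = np.log(f).T, np.log1p(-f).T
    snp_ll = haps[:, :, None] * logf[None] + (1 - haps[:, :, None]) * log1mf[None]

    post = np.empty((H, m, k))
    chrom = snps["chrom"].to_numpy()
    pos_m = snps["cm"].to_numpy() / 100.0
    for c in np.unique(chrom):
        idx = np.nonzero(chrom == c)[0]
        mc = len(idx)
        starts = _window_bounds(mc, params.window_snps)
        W = len(starts)
        # window emission log-likelihoods (H, W, k)
        ll = np.add.reduceat(snp_ll[:, idx, :], starts, axis=1)
        ll -= ll.max(axis=2, keepdims=True)
        emit = np.exp(ll)
        mids = np.array([pos_m[idx[s: s + params.window_snps]].mean() for s in starts])
        d = np.diff(mids)
        stay = np.exp(-params.switch_rate * np.maximum(d, 0.0))

        alpha = np.empty((W, H, k))
        a = emit[:, 0, :] / k
        a /= a.sum(axis=1, keepdims=True)
        alpha[0] = a
        for w in range(1, W):
            s = stay[w - 1]
            pred = s * alpha[w - 1] + (1 - s) / k
            a = pred * emit[:, w, :]
            a /= a.sum(axis=1, keepdims=True)
            alpha[w] = a
        beta = np.ones((H, k))
        po = np.empty((W, H, k))
        po[W - 1] = alpha[W - 1]
        for w in range(W - 2, -1, -1):
            s = stay[w]
            b = emit[:, w + 1, :] * beta
            beta = s * b + (1 - s) / k * b.sum(axis=1, keepdims=True)
            beta /= beta.max(axis=1, keepdims=True)
            g = alpha[w] * beta
            po[w] = g / g.sum(axis=1, keepdims=True)
        # expand windows back to SNPs
        reps = np.minimum(starts + params.window_snps, mc) - starts
        post[:, idx, :] = np.repeat(po.transpose(1, 0, 2), reps, axis=1)
    return post


def viterbi_path(posteriors: np.ndarray) -> np.ndarray:
    """Argmax-posterior ancestry labels per haplotype and SNP."""
    return np.argmax(posteriors, axis=2)


def average_pairs(
    configs: list[np.ndarray],
    sample_ids: list[str],
    snps: pd.DataFrame,
    ancestry_labels: tuple[str, ...],
) -> LocalAncestryField:
    """Average haplotype posteriors into diploid local-ancestry proportions.

    Each phase configuration is an (n, 2, m, k) posterior array (two
    haplotypes per individual); the field entry is the mean over
    configurations of the two-haplotype average, mirroring ancestry-state
    counting averaged across sampled haplotype pairs.
    """
    if len(configs) == 0:
        raise ValueError("at least one phase configuration required")
    shapes = {c.shape for c in map(np.asarray, configs)}
    if len(shapes) != 1:
        raise ValueError(f"phase configurations disagree in shape: {shapes}")
    (shape,) = shapes
    if len(shape) != 4 or shape[1] != 2:
        raise ValueError("each configuration must be (n, 2, m, k)")
    vals = np.mean([np.asarray(c).mean(axis=1) for c in configs], axis=0)
    vals = vals / vals.sum(axis=2, keepdims=True)
    return LocalAncestryField(vals, sample_ids, snps, ancestry_labels)


def global_from_local(field: LocalAncestryField) -> GlobalAncestry:
    """Unweighted genome-wide mean of local ancestry per individual."""
    return GlobalAncestry(field.values.mean(axis=1), field.sample_ids,
                          field.ancestry_labels)


def genotype_pca(g: GenotypeMatrix, n_components: int) -> pd.DataFrame:
    """Top principal components of the standardized genotype matrix.

    Missing dosages are mean-imputed per SNP; columns are centered by 2*phat
    and scaled by sqrt(2*phat*(1-phat)); eigenvectors (unit-norm left
    singular vectors) get a deterministic sign: the largest-magnitude SNP
    loading of each component is positive.  Returns a frame indexed by
    sample with columns ev1..evC, directly usable as regression covariates.
    """
    X = g.dosage.astype(float)
    X[g.dosage == MISSING] = np.nan
    mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = mean[inds[1]]
    phat = mean / 2.0
    scale = np.sqrt(2.0 * phat * (1.0 - phat))
    ok = scale > 0
    Z = (X[:, ok] - 2.0 * phat[ok]) / scale[ok]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    U, Vt = U[:, :n_components], Vt[:n_components]
    for j in range(n_components):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            U[:, j] *= -1.0
    return pd.DataFrame(U, index=g.samples,
                        columns=[f"ev{j + 1}" for j in range(n_components)])
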