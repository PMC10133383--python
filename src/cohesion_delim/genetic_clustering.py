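"""SNP replicate sets, one-hot encoding, VAE/PCA embeddings, cluster verdicts.

The molecular evidence for genetic exchangeability: per-locus alignments are
reduced to replicate single-SNP-per-locus genotype matrices, one-hot encoded,
and embedded into a 2-D Gaussian latent space by a small variational
autoencoder (plain NumPy; the data regime is tens of individuals so no GPU
framework is warranted).  Morphological trait tables go through a covariance
PCA.  A quantitative cluster assessment (silhouette + adjusted Rand index of
k-means against lineage labels) stands in for by-eye judgments of cluster
separation, with its thresholds recorded alongside every verdict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .synthetic_data import LocusAlignmentSet

__all__ = [
    "SNPMatrix",
    "LatentEmbedding",
    "PCAResult",
    "ClusterAssessment",
    "VAEConfig",
    "extract_snp_sets",
    "one_hot",
    "embed_vae",
    "embed_pca",
    "assess_clustering",
    "pairwise_assessments",
]

_ACGT = frozenset("ACGT")


@dataclass
class SNPMatrix:
    """Individuals x loci biallelic genotype calls (0/1/2; -1 = missing)."""

    set_id: int
    individuals: list[str]
    loci: list[str]
    genotypes: np.ndarray
    site_index: dict[str, int]  # chosen alignment column per locus
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.genotypes.shape != (len(self.individuals), len(self.loci)):
            raise ValueError("genotype matrix shape mismatch")

    def to_frame(self):
        """Individuals x loci genotype table (missing as -1)."""
        import pandas as pd

        return pd.DataFrame(self.genotypes, index=self.individuals, columns=self.loci)


@dataclass
class LatentEmbedding:
    individuals: list[str]
    mean: np.ndarray  # (n, 2)
    sd: np.ndarray  # (n, 2), strictly positive
    final_loss: float
    replicate_index: int
    seed: int
    loss_trajectory: np.ndarray | None = None


@dataclass
class PCAResult:
    scores: np.ndarray
    variance_fraction: np.ndarray
    loadings: np.ndarray
    columns: list[str]
    dropped_constant: list[str] = field(default_factory=list)


@dataclass
class ClusterAssessment:
    source: str
    silhouette: float
    ari: float
    verdict: str  # "separate" | "overlapping"
    silhouette_threshold: float
    ari_threshold: float
    labels: list[str] = field(default_factory=list)


# -- SNP extraction --------------------------------------------------------


def _locus_site_candidates(seqs: Mapping[str, str]) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Columns that are variable, biallelic, and ACGT-only, with (ref, alt).

    ``alt`` is the rarer allele among haplotypes (ties: the lexicographically
    later base).
    """
    names = list(seqs)
    mat = np.array([list(seqs[n]) for n in names])
    sites: list[int] = []
    alleles: list[tuple[str, str]] = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        uniq, counts = np.unique(col, return_counts=True)
        if len(uniq) != 2:
            continue
        if any(u not in _ACGT for u in uniq):
            continue
        order = np.argsort(counts, kind="stable")
        if counts[order[0]] == counts[order[1]]:
            ref, alt = sorted(uniq)  # tie: later base is alt
        else:
            alt, ref = uniq[order[0]], uniq[order[1]]
        sites.append(j)
        alleles.append((str(ref), str(alt)))
    return np.array(sites, dtype=int), alleles


def extract_snp_sets(
    aligns: LocusAlignmentSet,
    n_sets: int = 5,
    seed: int = 0,
) -> list[SNPMatrix]:
    """Replicate single-random-SNP-per-locus genotype matrices.

    Per locus the variable biallelic ACGT-only sites are identified once; each
    replicate set draws one of them uniformly.  Loci with no qualifying site
    are dropped from every set.  Genotypes are haplotype allele sums (0/1/2),
    missing (-1) when the individual lacks the locus.
    """
    if not aligns.loci:
        raise ValueError("no loci provided")
    rng = np.random.default_rng(seed)
    individuals = list(aligns.individual_lineage)
    locus_names = sorted(aligns.loci)

    per_locus: dict[str, tuple[np.ndarray, list[tuple[str, str]], dict[str, str]]] = {}
    for name in locus_names:
        seqs = aligns.loci[name]
        if not seqs:
            continue
        sites, alleles = _locus_site_candidates(seqs)
        if sites.size:
            per_locus[name] = (sites, alleles, seqs)
    if not per_locus:
        raise ValueError("no locus has a qualifying biallelic site")

    kept = list(per_locus)
    out: list[SNPMatrix] = []
    for s in range(n_sets):
        geno = np.full((len(individuals), len(kept)), -1, dtype=int)
        chosen: dict[str, int] = {}
        for li, name in enumerate(kept):
            sites, alleles, seqs = per_locus[name]
            pick = int(rng.integers(sites.size))
            j = int(sites[pick])
            _, alt = alleles[pick]
            chosen[name] = j
            for ii, ind in enumerate(individuals):
                h0, h1 = seqs.get(f"{ind}/0"), seqs.get(f"{ind}/1")
                if h0 is None or h1 is None:
                    continue
                geno[ii, li] = (h0[j] == alt) + (h1[j] == alt)
        out.append(
            SNPMatrix(
                set_id=s,
                individuals=individuals,
                loci=kept,
                genotypes=geno,
                site_index=chosen,
                meta={"seed": seed, "n_sets": n_sets},
            )
        )
    return out


def one_hot(snp: SNPMatrix) -> np.ndarray:
    """Encode genotypes as per-locus indicator triplets (missing -> zeros).

    Output shape ``(n_individuals, 3 * n_loci)``; column order is locus order
    (matrix order) crossed with genotype order 0, 1, 2.
    """
    g = snp.genotypes
    bad = (g < -1) | (g > 2)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"unexpected genotype code {g[i, j]} at individual "
            f"{snp.individuals[i]!r}, locus {snp.loci[j]!r}"
        )
    n, m = g.shape
    enc = np.zeros((n, m, 3))
    for code in (0, 1, 2):
        enc[:, :, code] = g == code
    return enc.reshape(n, 3 * m)


# -- variational autoencoder ----------------------------------------------


@dataclass
class VAEConfig:
    """Small-data VAE defaults (~tens of individuals, thousands of columns)."""

    hidden1: int | None = None  # default max(32, n_features // 10)
    hidden2: int = 16
    latent: int = 2
    epochs: int = 500
    learning_rate: float = 1e-3
    n_replicates: int = 3


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x: np.ndarray, fx: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, fx + 1.0)


class _NumpyVAE:
    """Two-hidden-layer Gaussian-latent VAE trained full-batch with Adam."""

    def __init__(self, d: int, cfg: VAEConfig, rng: np.random.Generator) -> None:
        h1 = cfg.hidden1 if cfg.hidden1 is not None else max(32, d // 10)
        h2, lat = cfg.hidden2, cfg.latent
        self.cfg = cfg
        self.rng = rng

        def glorot(fan_in, fan_out):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        self.p = {
            "W1": glorot(d, h1), "b1": np.zeros(h1),
            "W2": glorot(h1, h2), "b2": np.zeros(h2),
            "Wm": glorot(h2, lat), "bm": np.zeros(lat),
            "Wv": glorot(h2, lat), "bv": np.zeros(lat),
            "U1": glorot(lat, h2), "c1": np.zeros(h2),
            "U2": glorot(h2, h1), "c2": np.zeros(h1),
            "U3": glorot(h1, d), "c3": np.zeros(d),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.p.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.p.items()}
        self._adam_t = 0

    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.p
        h1 = _elu(X @ p["W1"] + p["b1"])
        h2 = _elu(h1 @ p["W2"] + p["b2"])
        return h2 @ p["Wm"] + p["bm"], h2 @ p["Wv"] + p["bv"]

    def step(self, X: np.ndarray) -> float:
        """One full-batch gradient step; returns the (mean per-sample) loss."""
        p = self.p
        n = X.shape[0]
        a1 = X @ p["W1"] + p["b1"]; h1 = _elu(a1)
        a2 = h1 @ p["W2"] + p["b2"]; h2 = _elu(a2)
        mu = h2 @ p["Wm"] + p["bm"]
        logvar = np.clip(h2 @ p["Wv"] + p["bv"], -10, 10)
        eps = self.rng.standard_normal(mu.shape)
        std = np.exp(0.5 * logvar)
        z = mu + eps * std
        a3 = z @ p["U1"] + p["c1"]; g1 = _elu(a3)
        a4 = g1 @ p["U2"] + p["c2"]; g2 = _elu(a4)
        logits = g2 @ p["U3"] + p["c3"]
        # stable BCE with logits
        bce = np.sum(np.maximum(logits, 0) - logits * X + np.log1p(np.exp(-np.abs(logits))))
        kl = -0.5 * np.sum(1 + logvar - mu**2 - np.exp(logvar))
        loss = (bce + kl) / n

        prob = 1.0 / (1.0 + np.exp(-logits))
        d_logits = (prob - X) / n
        gU3 = g2.T @ d_logits; gc3 = d_logits.sum(0)
        d_g2 = d_logits @ p["U3"].T * _elu_grad(a4, g2)
        gU2 = g1.T @ d_g2; gc2 = d_g2.sum(0)
        d_g1 = d_g2 @ p["U2"].T * _elu_grad(a3, g1)
        gU1 = z.T @ d_g1; gc1 = d_g1.sum(0)
        d_z = d_g1 @ p["U1"].T
        d_mu = d_z + mu / n
        d_logvar = d_z * eps * 0.5 * std + 0.5 * (np.exp(logvar) - 1) / n
        gWm = h2.T @ d_mu; gbm = d_mu.sum(0)
        gWv = h2.T @ d_logvar; gbv = d_logvar.sum(0)
        d_h2 = (d_mu @ p["Wm"].T + d_logvar @ p["Wv"].T) * _elu_grad(a2, h2)
        gW2 = h1.T @ d_h2; gb2 = d_h2.sum(0)
        d_h1 = d_h2 @ p["W2"].T * _elu_grad(a1, h1)
        gW1 = X.T @ d_h1; gb1 = d_h1.sum(0)

        grads = {
            "W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2,
            "Wm": gWm, "bm": gbm, "Wv": gWv, "bv": gbv,
            "U1": gU1, "c1": gc1, "U2": gU2, "c2": gc2,
            "U3": gU3, "c3": gc3,
        }
        self._adam_t += 1
        lr, b1m, b2m, epsn = self.cfg.learning_rate, 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self._adam_m[k] = b1m * self._adam_m[k] + (1 - b1m) * g
            self._adam_v[k] = b2m * self._adam_v[k] + (1 - b2m) * g**2
            mhat = self._adam_m[k] / (1 - b1m**self._adam_t)
            vhat = self._adam_v[k] / (1 - b2m**self._adam_t)
            self.p[k] -= lr * mhat / (np.sqrt(vhat) + epsn)
        return float(loss)


def embed_vae(
    encoded: np.ndarray,
    individuals: Sequence[str] | None = None,
    config: VAEConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    n_replicates: int | None = None,
) -> LatentEmbedding:
    """Train replicate VAEs and keep the one with the smallest final loss.

    Replicates use seeds spawned deterministically from ``seed``; replicates
    ending with a non-finite loss are discarded with a warning.
    """
    X = np.asarray(encoded, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 individuals to train")
    cfg = config or VAEConfig()
    if epochs is not None:
        cfg = VAEConfig(**{**cfg.__dict__, "epochs": epochs})
    if n_replicates is not None:
        cfg = VAEConfig(**{**cfg.__dict__, "n_replicates": n_replicates})
    if individuals is None:
        individuals = [f"ind_{i}" for i in range(X.shape[0])]

    best: LatentEmbedding | None = None
    for rep, child in enumerate(np.random.SeedSequence(seed).spawn(cfg.n_replicates)):
        rng = np.random.default_rng(child)
        vae = _NumpyVAE(X.shape[1], cfg, rng)
        traj = np.empty(cfg.epochs)
        ok = True
        for e in range(cfg.epochs):
            traj[e] = vae.step(X)
            if not np.isfinite(traj[e]):
                warnings.warn(f"replicate {rep} diverged (non-finite loss); discarded")
                ok = False
                break
        if not ok:
            continue
        mu, logvar = vae.encode(X)
        emb = LatentEmbedding(
            individuals=list(individuals),
            mean=mu,
            sd=np.exp(0.5 * np.clip(logvar, -10, 10)),
            final_loss=float(traj[-1]),
            replicate_index=rep,
            seed=seed,
            loss_trajectory=traj,
        )
        if best is None or emb.final_loss < best.final_loss:
            best = emb
    if best is None:
        raise RuntimeError("all VAE replicates diverged")
    return best


# -- PCA -------------------------------------------------------------------


def embed_pca(
    table: np.ndarray,
    log_transform: bool = False,
    scale: bool = False,
    columns: Sequence[str] | None = None,
) -> PCAResult:
    """Covariance PCA with mean imputation and a deterministic sign convention.

    Missing values are mean-imputed per column (documented); with
    ``log_transform`` values must be strictly positive.  Constant columns are
    dropped with a warning.  Each component's largest-magnitude loading is
    made positive.
    """
    X = np.asarray(table, dtype=float).copy()
    if columns is None:
        columns = [f"col_{j}" for j in range(X.shape[1])]
    columns = list(columns)
    if log_transform:
        if np.nanmin(X) <= 0:
            raise ValueError("log transform requires strictly positive values")
        X = np.log(X)
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [c for c, k in zip(columns, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant column(s): {dropped}")
        X = X[:, keep]
        columns = [c for c, k in zip(columns, keep) if k]
        sd = sd[keep]
    X = X - X.mean(axis=0)
    if scale:
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|loading| entry of each component is positive
    for c in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u * s
    var = s**2
    return PCAResult(
        scores=scores,
        variance_fraction=var / var.sum(),
        loadings=vt.T,
        columns=columns,
        dropped_constant=dropped,
    )


# -- cluster assessment ----------------------------------------------------


def assess_clustering(
    points: np.ndarray,
    labels: Sequence[str],
    silhouette_threshold: float = 0.35,
    ari_threshold: float = 0.9,
    source: str = "embedding",
    seed: int = 0,
) -> ClusterAssessment:
    """Quantified "separate vs overlapping" verdict for a 2-D embedding.

    Separate iff the label silhouette reaches ``silhouette_threshold`` AND the
    adjusted Rand index of k-means (k = number of labels) against the labels
    reaches ``ari_threshold``.
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import adjusted_rand_score, silhouette_score

    labels = list(labels)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("need at least two distinct labels")
    pts = np.asarray(points, dtype=float)
    sil = float(silhouette_score(pts, labels))
    km = KMeans(n_clusters=len(uniq), n_init=10, random_state=seed).fit_predict(pts)
    ari = float(adjusted_rand_score(labels, km))
    verdict = "separate" if (sil >= silhouette_threshold and ari >= ari_threshold) else "overlapping"
    return ClusterAssessment(
        source=source,
        silhouette=sil,
        ari=ari,
        verdict=verdict,
        silhouette_threshold=silhouette_threshold,
        ari_threshold=ari_threshold,
        labels=uniq,
    )


def pairwise_assessments(
    points: np.ndarray,
    labels: Sequence[str],
    **kwargs,
) -> dict[tuple[str, str], ClusterAssessment]:
    """Per-lineage-pair verdicts from one embedding."""
    labels = np.asarray(list(labels))
    uniq = sorted(set(labels.tolist()))
    out = {}
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            sel = np.isin(labels, [uniq[i], uniq[j]])
            out[(uniq[i], uniq[j])] = assess_clustering(
                np.asarray(points)[sel], labels[sel].tolist(), **kwargs
            )
    return out
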