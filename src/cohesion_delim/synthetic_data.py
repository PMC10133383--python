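"""Synthetic landscapes, occurrences, locus alignments, and trait tables.

Everything downstream of this module (raster prep, SDMs, niche tests, SNP
clustering, decisions) can be exercised against data with known ground truth,
so no external rasters, occurrence databases, or sequence archives are needed.

Climate fields are built by Gaussian-kernel smoothing of white noise followed
by eigen-factor mixing to impose a target inter-layer correlation.  Genetic
divergence follows the Balding–Nichols style F-model: daughter allele
frequencies are Beta-distributed around the ancestral frequency with a drift
parameter ``F`` per branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .climate_prep import RasterStack

__all__ = [
    "NicheParams",
    "DivergenceSpec",
    "OccurrenceSet",
    "LocusAlignmentSet",
    "simulate_climate_stack",
    "simulate_occurrences",
    "simulate_locus_alignments",
    "simulate_trait_table",
    "suitability_map",
]


@dataclass
class NicheParams:
    """Gaussian climatic niche: per-layer optimum and tolerance.

    Suitability at environment ``x`` is
    ``max_suitability * prod_l exp(-(x_l - opt_l)^2 / (2 tol_l^2))``,
    which always lies in ``[0, 1]``.
    """

    optima: np.ndarray
    tolerances: np.ndarray
    max_suitability: float = 1.0

    def __post_init__(self) -> None:
        self.optima = np.atleast_1d(np.asarray(self.optima, dtype=float))
        self.tolerances = np.atleast_1d(np.asarray(self.tolerances, dtype=float))
        if self.optima.shape != self.tolerances.shape:
            raise ValueError("optima and tolerances must have matching length")
        if np.any(self.tolerances <= 0):
            raise ValueError("tolerances must be strictly positive")
        if not (0 < self.max_suitability <= 1):
            raise ValueError("max_suitability must be in (0, 1]")

    def suitability(self, env: np.ndarray) -> np.ndarray:
        """Suitability for environment rows ``(n_points, n_layers)``."""
        env = np.atleast_2d(env)
        z = (env - self.optima) / self.tolerances
        return self.max_suitability * np.exp(-0.5 * (z**2).sum(axis=1))


@dataclass
class DivergenceSpec:
    """Lineage tree (nested pairs of labels) plus per-branch drift F.

    ``tree`` is a label for a leaf or a 2-tuple of subtrees, e.g.
    ``("North", ("Central", "South"))``.  ``f_branch`` is either a single
    drift value applied to every branch or a mapping from a clade key (the
    sorted, "+"-joined leaf labels of the subtree at the branch's lower end)
    to a drift value.  ``F = 0`` means panmixia along the branch (daughter
    frequency equals the parental frequency exactly).
    """

    tree: object
    f_branch: float | Mapping[str, float] = 0.2
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_freq_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("ancestral_freq_range must be an ordered subinterval of [0, 1]")
        for f in self._all_f_values():
            if not (0 <= f < 1):
                raise ValueError("every branch F must lie in [0, 1)")

    def _all_f_values(self) -> list[float]:
        if isinstance(self.f_branch, Mapping):
            return list(self.f_branch.values())
        return [float(self.f_branch)]

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node) -> None:
            if isinstance(node, (tuple, list)):
                for child in node:
                    walk(child)
            else:
                out.append(str(node))

        walk(self.tree)
        return out

    def branch_f(self, node) -> float:
        if isinstance(self.f_branch, Mapping):
            key = "+".join(sorted(_leaves_of(node)))
            return float(self.f_branch.get(key, 0.0))
        return float(self.f_branch)


def _leaves_of(node) -> list[str]:
    if isinstance(node, (tuple, list)):
        out: list[str] = []
        for child in node:
            out.extend(_leaves_of(child))
        return out
    return [str(node)]


@dataclass
class OccurrenceSet:
    """Occurrence records for one lineage on the planar grid."""

    lineage: str
    x: np.ndarray
    y: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_1d(np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.x.size


@dataclass
class LocusAlignmentSet:
    """Per-locus haplotype alignments (two phased sequences per individual).

    ``loci`` maps locus name -> dict of ``"<individual>/<0|1>"`` -> sequence.
    """

    loci: dict[str, dict[str, str]]
    individual_lineage: dict[str, str]
    completeness: float
    provenance: dict = field(default_factory=dict)

    @property
    def individuals(self) -> list[str]:
        return list(self.individual_lineage)

    def write_fasta_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, seqs in self.loci.items():
            with open(path / f"{name}.fasta", "w") as fh:
                for hap, seq in seqs.items():
                    fh.write(f">{hap}\n{seq}\n")


# -- climate ---------------------------------------------------------------


def simulate_climate_stack(
    n_layers: int,
    grid: tuple[int, int] = (50, 50),
    autocorr_length: float = 5.0,
    target_corr: np.ndarray | None = None,
    seed: int = 0,
) -> RasterStack:
    """Spatially autocorrelated standardized climate layers.

    Each layer is white noise smoothed with a Gaussian kernel of scale
    ``autocorr_length`` (cells) and standardized to mean 0, sd 1.  If
    ``target_corr`` is given, layers are mixed with an eigen-factor of the
    matrix so realized inter-layer Pearson correlations approximate it.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if autocorr_length < 0:
        raise ValueError("autocorr_length must be >= 0")
    rows, cols = grid
    rng = np.random.default_rng(seed)
    fields = rng.standard_normal((n_layers, rows, cols))
    if autocorr_length > 0:
        fields = np.stack(
            [gaussian_filter(f, sigma=autocorr_length, mode="reflect") for f in fields]
        )
    flat = fields.reshape(n_layers, -1)
    flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(axis=1, keepdims=True)

    if target_corr is not None:
        target_corr = np.asarray(target_corr, dtype=float)
        if target_corr.shape != (n_layers, n_layers):
            raise ValueError("target_corr must be n_layers x n_layers")
        if not np.allclose(target_corr, target_corr.T):
            raise ValueError("target_corr must be symmetric")
        w, v = np.linalg.eigh(target_corr)
        if w.min() < -1e-8:
            raise ValueError("target_corr must be positive semi-definite")
        mixer = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
        # Decorrelate finite-sample noise first so the imposed structure is clean.
        cov = np.cov(flat)
        if n_layers > 1:
            wn, vn = np.linalg.eigh(cov)
            whiten = vn @ np.diag(1.0 / np.sqrt(np.clip(wn, 1e-12, None))) @ vn.T
            flat = whiten @ flat
        flat = mixer @ flat
        sd = flat.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        flat = (flat - flat.mean(axis=1, keepdims=True)) / sd

    values = flat.reshape(n_layers, rows, cols)
    return RasterStack(
        names=[f"env{i + 1}" for i in range(n_layers)],
        values=values,
        mask=np.ones((rows, cols), dtype=bool),
        origin=(0.0, float(rows)),  # grid occupies x in [0, cols], y in [0, rows]
    )


def suitability_map(stack: RasterStack, niche: NicheParams) -> np.ndarray:
    """True suitability over the grid (NaN on masked cells)."""
    env = stack.values.reshape(stack.n_layers, -1).T
    s = niche.suitability(env).reshape(stack.shape)
    return np.where(stack.mask, s, np.nan)


def simulate_occurrences(
    stack: RasterStack,
    niches: Mapping[str, NicheParams],
    n_per_lineage: Mapping[str, int] | int,
    region_mask: Mapping[str, np.ndarray] | None = None,
    seed: int = 0,
) -> dict[str, OccurrenceSet]:
    """Sample occurrences with probability proportional to niche suitability.

    Cells are drawn (with replacement) proportionally to suitability among
    valid cells, optionally restricted per lineage by ``region_mask``;
    coordinates are cell centers jittered uniformly within the cell.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, OccurrenceSet] = {}
    xs, ys = stack.cell_centers()
    for lineage, niche in niches.items():
        n = n_per_lineage[lineage] if isinstance(n_per_lineage, Mapping) else int(n_per_lineage)
        if n < 1:
            raise ValueError(f"n_per_lineage must be >= 1 for lineage {lineage!r}")
        suit = suitability_map(stack, niche)
        allowed = stack.mask.copy()
        if region_mask is not None and lineage in region_mask:
            allowed &= np.asarray(region_mask[lineage], dtype=bool)
        probs = np.where(allowed, np.nan_to_num(suit), 0.0).ravel()
        total = probs.sum()
        if total <= 0:
            raise ValueError(f"all-zero suitability over the sampling mask for lineage {lineage!r}")
        cells = rng.choice(probs.size, size=n, replace=True, p=probs / total)
        jx = rng.uniform(-0.5, 0.5, size=n) * stack.cell_size
        jy = rng.uniform(-0.5, 0.5, size=n) * stack.cell_size
        out[lineage] = OccurrenceSet(
            lineage=lineage,
            x=xs.ravel()[cells] + jx,
            y=ys.ravel()[cells] + jy,
            provenance={"seed": seed, "n": n, "niche_optima": niche.optima.tolist()},
        )
    return out


# -- genetics --------------------------------------------------------------


def _descend_frequencies(node, p: np.ndarray, spec: DivergenceSpec, rng) -> dict[str, np.ndarray]:
    """Walk the lineage tree drawing Beta-distributed daughter frequencies."""
    if not isinstance(node, (tuple, list)):
        return {str(node): p}
    out: dict[str, np.ndarray] = {}
    for child in node:
        f = spec.branch_f(child)
        if f == 0:
            child_p = p.copy()
        else:
            a = p * (1 - f) / f
            b = (1 - p) * (1 - f) / f
            # Beta parameters must be positive; clip p away from the boundary.
            eps = 1e-9
            a = np.clip(a, eps, None)
            b = np.clip(b, eps, None)
            child_p = rng.beta(a, b)
        out.update(_descend_frequencies(child, child_p, spec, rng))
    return out


BASES = np.array(list("ACGT"))


def simulate_locus_alignments(
    spec: DivergenceSpec,
    n_individuals_per_lineage: int = 5,
    n_loci: int = 100,
    sites_per_locus: int = 40,
    prop_variable: float = 0.2,
    completeness: float = 1.0,
    seed: int = 0,
) -> LocusAlignmentSet:
    """Simulate phased per-locus alignments under the F-model.

    Variable sites: ancestral frequency ``p ~ Uniform(ancestral_freq_range)``;
    each lineage's frequency is Beta-distributed around it with the branch's
    drift ``F``; haplotype alleles are Bernoulli draws.  Invariant sites are
    identical across all haplotypes.  Each individual is present at a locus
    with probability ``completeness`` (both haplotypes drop together).
    """
    if not (0 < completeness <= 1):
        raise ValueError("completeness must lie in (0, 1]")
    if not (0 <= prop_variable <= 1):
        raise ValueError("prop_variable must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lineages = spec.leaves()
    individuals = {
        f"{lin}_{i:02d}": lin for lin in lineages for i in range(n_individuals_per_lineage)
    }
    n_var = int(round(prop_variable * sites_per_locus))
    lo, hi = spec.ancestral_freq_range

    loci: dict[str, dict[str, str]] = {}
    for locus_i in range(n_loci):
        anc_p = rng.uniform(lo, hi, size=n_var)
        freqs = _descend_frequencies(spec.tree, anc_p, spec, rng)
        # Allele-to-base maps per variable site (ref != alt).
        ref = rng.integers(0, 4, size=sites_per_locus)
        alt = (ref + rng.integers(1, 4, size=sites_per_locus)) % 4
        var_sites = rng.choice(sites_per_locus, size=n_var, replace=False) if n_var else np.array([], dtype=int)
        backbone = BASES[ref]

        present = {ind: rng.random() < completeness for ind in individuals}
        seqs: dict[str, str] = {}
        for ind, lin in individuals.items():
            if not present[ind]:
                continue
            p_lin = freqs[lin]
            for hap in (0, 1):
                alleles = (rng.random(n_var) < p_lin).astype(int)
                seq = backbone.copy()
                if n_var:
                    seq[var_sites] = np.where(alleles == 1, BASES[alt[var_sites]], BASES[ref[var_sites]])
                seqs[f"{ind}/{hap}"] = "".join(seq)
        loci[f"locus_{locus_i:04d}"] = seqs

    return LocusAlignmentSet(
        loci=loci,
        individual_lineage=individuals,
        completeness=completeness,
        provenance={
            "seed": seed,
            "n_loci": n_loci,
            "sites_per_locus": sites_per_locus,
            "prop_variable": prop_variable,
            "f_branch": spec.f_branch if not isinstance(spec.f_branch, Mapping) else dict(spec.f_branch),
        },
    )


# -- morphology ------------------------------------------------------------


def simulate_trait_table(
    n_per_lineage: int = 10,
    n_traits: int = 25,
    lineage_shift: float = 0.0,
    lineages: Sequence[str] = ("North", "Central", "South"),
    seed: int = 0,
):
    """Log-normal continuous trait table with a shared within-individual size factor.

    ``lineage_shift`` displaces lineage means (in units of the size-factor sd)
    on the log scale; 0 reproduces fully overlapping lineage distributions.
    Returns a pandas DataFrame indexed by individual with a ``lineage`` column
    followed by strictly positive trait columns.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    size_sd = 0.2
    trait_base = rng.uniform(0.5, 2.0, size=n_traits)  # per-trait log-mean
    rows = []
    index = []
    lineage_col = []
    for li, lin in enumerate(lineages):
        lin_mean = li * lineage_shift * size_sd
        for i in range(n_per_lineage):
            size = rng.normal(lin_mean, size_sd)
            noise = rng.normal(0, 0.08, size=n_traits)
            rows.append(np.exp(trait_base + size + noise))
            index.append(f"{lin}_{i:02d}")
            lineage_col.append(lin)
    df = pd.DataFrame(rows, index=index, columns=[f"trait_{t + 1:02d}" for t in range(n_traits)])
    df.insert(0, "lineage", lineage_col)
    return df
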