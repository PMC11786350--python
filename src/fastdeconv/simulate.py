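"""Synthetic spatial transcriptomics with known per-spot ground truth.

Each spot is built the way low-resolution platforms mix cells: a region-
specific Dirichlet draw fixes the spot's cell-type proportions, a fixed
number of cells is assigned to types multinomially, every cell's counts are
drawn from a negative-binomial around its type's mean expression profile,
and the spot vector is the sum over its cells. The realized cell-count
fractions are the ground-truth proportion matrix against which
deconvolution accuracy is scored.

Cell-type mean profiles are themselves synthetic: a shared log-normal
baseline with a disjoint block of marker genes per type elevated by a fold
factor. Real single-cell pools can be substituted through the same
interface by passing custom signatures.

The built-in :func:`mob_table1_design` mirrors a three-layer olfactory-bulb
benchmark: 75 granule-layer spots (astrocyte-dominant, alpha = (1, 3)),
140 mitral-layer spots (neuron-dominant, alpha = (3, 1)) and 45 nerve-layer
spots (balanced, alpha = (1, 1)), 260 spots in total, arranged as
concentric annuli on a disc with the granule layer innermost. Before
deconvolution the gene set is reduced to differentially expressed genes by
a per-gene Wilcoxon rank-sum test at a Benjamini-Hochberg adjusted
p < 1e-5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import SpotGeometry
from .solver import ExpressionMatrix

__all__ = [
    "Region",
    "SimulationDesign",
    "Signatures",
    "SimulatedDataset",
    "mob_table1_design",
    "make_signatures",
    "simulate_dataset",
    "de_gene_filter",
]


@dataclass
class Region:
    """A tissue region: name, number of spots, Dirichlet concentration."""

    name: str
    n_spots: int
    alpha: tuple[float, ...]


@dataclass
class SimulationDesign:
    """Study design for a simulated dataset.

    ``cells_per_spot`` is the number of single cells pooled into each spot
    (default 10, a plausible load for 100-micron spots).
    ``marker_fraction`` of the genes are split into disjoint per-type marker
    blocks whose mean expression is multiplied by ``effect_size``.
    """

    regions: list[Region]
    n_genes: int = 500
    n_cell_types: int = 2
    cells_per_spot: int = 10
    marker_fraction: float = 0.2
    effect_size: float = 4.0
    dispersion: float = 0.5
    seed: int = 0
    layout: str = "concentric"
    cell_type_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("design needs at least one region")
        for reg in self.regions:
            if len(reg.alpha) != self.n_cell_types:
                raise ValueError(
                    f"region {reg.name!r}: alpha has length {len(reg.alpha)}, "
                    f"expected {self.n_cell_types}"
                )
            if any(a <= 0 for a in reg.alpha):
                raise ValueError(f"region {reg.name!r}: alpha must be positive")
            if reg.n_spots < 1:
                raise ValueError(f"region {reg.name!r}: n_spots must be >= 1")
        if not 0 < self.marker_fraction < 1:
            raise ValueError("marker_fraction must lie in (0, 1)")
        if self.cells_per_spot < 1:
            raise ValueError("cells_per_spot must be >= 1")

    @property
    def n_spots(self) -> int:
        return sum(r.n_spots for r in self.regions)


@dataclass
class Signatures:
    """Per-type mean expression profiles and the NB dispersion used to
    sample cells around them."""

    means: np.ndarray  # genes x types
    dispersion: float
    marker_blocks: list[np.ndarray] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    X: ExpressionMatrix
    H_true: np.ndarray  # spots x types, rows sum to 1
    W_true: np.ndarray  # genes x types mean signatures
    geometry: SpotGeometry
    region_labels: np.ndarray
    cell_matrix: np.ndarray  # genes x cells, for DE filtering
    cell_labels: np.ndarray  # type index per cell


def mob_table1_design(**overrides) -> SimulationDesign:
    """Three-layer, two-cell-type olfactory-bulb benchmark design."""
    defaults = dict(
        regions=[
            Region("granule cell layer", 75, (1.0, 3.0)),
            Region("mitral cell layer", 140, (3.0, 1.0)),
            Region("nerve layer", 45, (1.0, 1.0)),
        ],
        n_genes=500,
        n_cell_types=2,
        cells_per_spot=10,
        marker_fraction=0.2,
        effect_size=4.0,
        cell_type_names=("neurons", "astrocytes"),
    )
    defaults.update(overrides)
    return SimulationDesign(**defaults)


def make_signatures(
    n_genes: int,
    n_cell_types: int,
    marker_fraction: float = 0.2,
    effect_size: float = 4.0,
    seed: int = 0,
    dispersion: float = 0.5,
) -> Signatures:
    """Synthetic mean expression profiles with disjoint marker blocks.

    Baseline gene means are log-normal (mu = 0, sigma = 1); each type's
    marker block of ``floor(marker_fraction * n_genes / n_cell_types)``
    genes has its mean multiplied by ``effect_size``.
    """
    block = int(marker_fraction * n_genes) // n_cell_types
    if block * n_cell_types > n_genes:
        raise ValueError("marker blocks exceed the number of genes")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    means = np.tile(base[:, None], (1, n_cell_types))
    blocks = []
    for k in range(n_cell_types):
        idx = np.arange(k * block, (k + 1) * block)
        means[idx, k] *= effect_size
        blocks.append(idx)
    return Signatures(means=means, dispersion=dispersion, marker_blocks=blocks)


def _concentric_layout(
    design: SimulationDesign, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place regions as annuli of equal width on a unit disc, first region
    innermost; returns x, y and a per-spot intensity level."""
    n_regions = len(design.regions)
    radii = np.linspace(0.0, 1.0, n_regions + 1)
    levels = np.linspace(0.3, 0.8, n_regions)
    xs, ys, zs = [], [], []
    for i, reg in enumerate(design.regions):
        # uniform over the annulus area
        r = np.sqrt(rng.uniform(radii[i] ** 2, radii[i + 1] ** 2, reg.n_spots))
        theta = rng.uniform(0, 2 * np.pi, reg.n_spots)
        xs.append(r * np.cos(theta))
        ys.append(r * np.sin(theta))
        zs.append(
            np.clip(levels[i] + rng.normal(0.0, 0.02, reg.n_spots), 0.0, 1.0)
        )
    return np.concatenate(xs), np.concatenate(ys), np.concatenate(zs)


def simulate_dataset(
    design: SimulationDesign, signatures: Signatures | None = None
) -> SimulatedDataset:
    """Draw a dataset from the design; same design seed, same bits.

    Per spot: proportions ~ Dirichlet(region alpha); cell counts per type
    ~ Multinomial(cells_per_spot, proportions); each cell's counts are
    negative-binomial (gamma-Poisson) around its type's mean profile; the
    spot expression vector is the sum over its cells. ``H_true`` holds the
    realized cell-count fractions.
    """
    rng = np.random.default_rng(design.seed)
    if signatures is None:
        signatures = make_signatures(
            design.n_genes,
            design.n_cell_types,
            design.marker_fraction,
            design.effect_size,
            seed=design.seed,
            dispersion=design.dispersion,
        )
    means = signatures.means
    if means.shape != (design.n_genes, design.n_cell_types):
        raise ValueError(
            f"signatures shape {means.shape} does not match design "
            f"({design.n_genes}, {design.n_cell_types})"
        )

    m = design.n_spots
    c = design.cells_per_spot
    H_true = np.empty((m, design.n_cell_types))
    region_labels = np.empty(m, dtype=object)
    cell_labels = np.empty(m * c, dtype=int)
    spot = 0
    for reg in design.regions:
        p = rng.dirichlet(reg.alpha, size=reg.n_spots)
        counts = np.array([rng.multinomial(c, pi) for pi in p])
        H_true[spot : spot + reg.n_spots] = counts / c
        region_labels[spot : spot + reg.n_spots] = reg.name
        for s in range(reg.n_spots):
            cell_labels[(spot + s) * c : (spot + s + 1) * c] = np.repeat(
                np.arange(design.n_cell_types), counts[s]
            )
        spot += reg.n_spots

    # gamma-Poisson mixture: var = mu + dispersion * mu^2
    phi = signatures.dispersion
    mu = means[:, cell_labels]  # genes x cells
    if phi > 0:
        shape = 1.0 / phi
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    cell_matrix = rng.poisson(lam).astype(float)

    X = cell_matrix.reshape(design.n_genes, m, c).sum(axis=2)

    x, y, z = _concentric_layout(design, rng)
    spot_ids = np.array([f"spot_{i:04d}" for i in range(m)])
    gene_ids = np.array([f"gene_{i:04d}" for i in range(design.n_genes)])
    geometry = SpotGeometry(spot_ids=spot_ids, x=x, y=y, z=z)
    return SimulatedDataset(
        X=ExpressionMatrix(X, gene_ids, spot_ids),
        H_true=H_true,
        W_true=means,
        geometry=geometry,
        region_labels=np.asarray(region_labels, dtype=str),
        cell_matrix=cell_matrix,
        cell_labels=cell_labels,
    )


def de_gene_filter(
    cell_matrix: np.ndarray,
    cell_labels: np.ndarray,
    alpha_cutoff: float = 1e-5,
) -> np.ndarray:
    """Indices of genes differentially expressed between cell types.

    Per gene, a two-sample Wilcoxon rank-sum (Mann-Whitney U) test compares
    each cell type against the rest (for two types the two directions
    coincide); the smallest p-value per gene is Benjamini-Hochberg adjusted
    and genes with adjusted p below ``alpha_cutoff`` are retained.
    """
    cell_matrix = np.asarray(cell_matrix, dtype=float)
    cell_labels = np.asarray(cell_labels)
    types, counts = np.unique(cell_labels, return_counts=True)
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    if counts.min() < 2:
        small = types[counts.argmin()]
        raise ValueError(f"cell type {small!r} has fewer than 2 cells")

    one_vs_rest = types if len(types) > 2 else types[:1]
    pvals = np.ones(cell_matrix.shape[0])
    for t in one_vs_rest:
        mask = cell_labels == t
        res = stats.mannwhitneyu(
            cell_matrix[:, mask],
            cell_matrix[:, ~mask],
            axis=1,
            alternative="two-sided",
        )
        pvals = np.minimum(pvals, res.pvalue)
    adjusted = stats.false_discovery_control(pvals, method="bh")
    return np.flatnonzero(adjusted < alpha_cutoff)
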