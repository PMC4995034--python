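"""Synthetic wing-landmark datasets with hierarchical taxonomic structure.

The generator emulates the design of the mosquito wing study the package
reproduces: 12 species in 3 genera (plus an optional outgroup), each specimen
an 18-landmark wing configuration.  Every specimen's shape is built in the
tangent space at a template wing as

    template + genus offset + subgenus offset + species offset
             + b * (log size - mean log size) + isotropic landmark noise,

then rendered at its centroid size and rigidly perturbed (random rotation and
translation) so that downstream Procrustes superimposition is exercised
non-trivially.  Taxon offsets are drawn once per taxon (fixed effects within a
dataset) in the tangent space at the template; landmark noise is isotropic
Gaussian per coordinate.

Allometry calibration
---------------------
The allometric direction ``b`` is a fixed unit tangent vector whose magnitude
is set analytically so the expected fraction of total shape variance
attributable to size equals ``allometry_fraction``.  With m = 2k coordinates,
t = m - 4 tangent dimensions surviving superimposition (translation, rotation
and scale removed), per-level offset variances sigma_l^2 and level group-size
weights w, the non-allometric variance is

    v_rest = t * (sigma_w^2 + sum_l sigma_l^2 * (1 - sum w^2)),

the log-size variance var_z is the log-normal variance plus the variance of
the log of the uniform nuisance scale (which multiplies the realized size and
therefore carries allometric signal), and

    |b|^2 = f / (1 - f) * v_rest / var_z.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .landmark_io import LandmarkConfiguration, ShapeDataset

#: stylized 18-landmark wing template (outline landmarks 1-10 from base along
#: the costa to the apex and back along the posterior margin; 11-18 interior
#: vein intersections).  Any non-degenerate template suffices: all analyses
#: are relative to the generator's own parameters.
TEMPLATE_WING = np.array([
    [0.00, 0.50],
    [1.20, 0.75],
    [2.40, 0.92],
    [3.40, 0.85],
    [4.00, 0.60],
    [3.60, 0.35],
    [3.00, 0.18],
    [2.20, 0.08],
    [1.40, 0.05],
    [0.60, 0.12],
    [0.90, 0.40],
    [1.60, 0.45],
    [2.10, 0.55],
    [2.60, 0.50],
    [3.00, 0.62],
    [3.10, 0.40],
    [2.50, 0.30],
    [1.80, 0.25],
])

#: the study design: (genus, subgenus, species, n) for the 12 ingroup species
STUDY_TAXA = (
    ("Aedes", "Stegomyia", "Ae_aegypti", 28),
    ("Aedes", "Stegomyia", "Ae_albopictus", 23),
    ("Aedes", "Ochlerotatus", "Ae_fluviatilis", 30),
    ("Aedes", "Ochlerotatus", "Ae_scapularis", 23),
    ("Anopheles", "Kerteszia", "An_cruzii", 22),
    ("Anopheles", "Nyssorhynchus", "An_darlingi", 30),
    ("Anopheles", "Nyssorhynchus", "An_strodei", 28),
    ("Culex", "Culex", "Cx_chidesteri", 28),
    ("Culex", "Culex", "Cx_dolosus", 29),
    ("Culex", "Culex", "Cx_eduardoi", 14),
    ("Culex", "Culex", "Cx_nigripalpus", 29),
    ("Culex", "Culex", "Cx_quinquefasciatus", 28),
)

OUTGROUP_TAXON = ("Wyeomyia", "Wyeomyia", "Wy_oblita", 20)


@dataclass
class TaxonSpec:
    genus: str
    subgenus: str
    species: str
    n: int


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic dataset.

    Effect scales are per-coordinate standard deviations in Procrustes
    (tangent-space) units; the defaults give genus >> subgenus >> species
    mean-shape offsets relative to within-species noise, so pairwise
    reclassification accuracies span roughly chance-to-perfect across
    taxonomic levels.
    """

    taxa: list = field(default_factory=lambda: [TaxonSpec(*t) for t in STUDY_TAXA])
    genus_offset_sd: float = 0.012
    subgenus_offset_sd: float = 0.005
    species_offset_sd: float = 0.003
    within_species_sd: float = 0.010
    allometry_fraction: float = 0.0591
    mean_log_size: float = math.log(300.0)   # arbitrary image units (~pixels)
    log_size_sd: float = 0.08
    rotation_range_deg: float = 30.0
    translation_range: float = 10.0
    scale_range: tuple = (0.8, 1.25)
    seed: int = 0

    def __post_init__(self):
        self.taxa = [t if isinstance(t, TaxonSpec) else TaxonSpec(**t) if isinstance(t, dict)
                     else TaxonSpec(*t) for t in self.taxa]
        if self.within_species_sd <= 0:
            raise ValueError("within_species_sd must be positive")
        if not (0 <= self.allometry_fraction < 1):
            raise ValueError("allometry_fraction must lie in [0, 1)")
        for t in self.taxa:
            if t.n < 2:
                raise ValueError(f"species {t.species!r}: sample size must be >= 2")
        self.scale_range = tuple(self.scale_range)
        if self.scale_range[0] <= 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError(f"invalid scale_range {self.scale_range}")

    @property
    def total_specimens(self) -> int:
        return sum(t.n for t in self.taxa)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorSpec":
        return cls(**json.loads(Path(path).read_text()))


def make_default_spec(seed: int, outgroup: bool = False) -> GeneratorSpec:
    """The study-design preset: 3 genera, 12 species, Table-1 sample sizes,
    5.91% allometric shape variance; optionally 20 outgroup specimens."""
    taxa = [TaxonSpec(*t) for t in STUDY_TAXA]
    if outgroup:
        taxa.append(TaxonSpec(*OUTGROUP_TAXON))
    spec = GeneratorSpec(taxa=taxa, seed=seed)
    assert spec.genus_offset_sd >= spec.subgenus_offset_sd >= spec.species_offset_sd
    return spec


def _log_uniform_variance(a: float, b: float) -> float:
    """Variance of log X for X ~ Uniform(a, b) (closed form)."""
    if b == a:
        return 0.0
    width = b - a

    def _int_log(x):   # integral of log
        return x * (math.log(x) - 1.0)

    def _int_log2(x):  # integral of log^2
        lx = math.log(x)
        return x * (lx * lx - 2.0 * lx + 2.0)

    mean = (_int_log(b) - _int_log(a)) / width
    mean2 = (_int_log2(b) - _int_log2(a)) / width
    return mean2 - mean * mean


def _log_uniform_mean(a: float, b: float) -> float:
    if b == a:
        return math.log(a)
    return (b * (math.log(b) - 1.0) - a * (math.log(a) - 1.0)) / (b - a)


def _similarity_projector(template_flat: np.ndarray, k: int) -> np.ndarray:
    """Projector onto the tangent space at the (centred, unit-size) template:
    the orthocomplement of translation, scaling, and rotation directions."""
    basis = np.zeros((4, 2 * k))
    basis[0, 0::2] = 1.0 / math.sqrt(k)          # x-translation
    basis[1, 1::2] = 1.0 / math.sqrt(k)          # y-translation
    basis[2] = template_flat                     # scaling (unit norm)
    rot = np.empty_like(template_flat)           # infinitesimal rotation
    rot[0::2] = -template_flat[1::2]
    rot[1::2] = template_flat[0::2]
    basis[3] = rot
    q, _ = np.linalg.qr(basis.T)
    return np.eye(2 * k) - q @ q.T


def _sum_sq_weights(spec: GeneratorSpec, key) -> float:
    """sum over groups of (n_group / N)^2 at a taxonomy level."""
    totals: dict = {}
    for t in spec.taxa:
        totals[key(t)] = totals.get(key(t), 0) + t.n
    n = spec.total_specimens
    return sum((v / n) ** 2 for v in totals.values())


def expected_size_log_variance(spec: GeneratorSpec) -> float:
    """Variance of realized log centroid size (log-normal draw times the
    uniform nuisance scale)."""
    return spec.log_size_sd ** 2 + _log_uniform_variance(*spec.scale_range)


def allometric_magnitude(spec: GeneratorSpec, k: int | None = None) -> float:
    """|b|: analytic scaling of the allometric vector (see module docstring)."""
    f = spec.allometry_fraction
    if f == 0:
        return 0.0
    if k is None:
        k = TEMPLATE_WING.shape[0]
    dim_t = 2 * k - 4
    v_rest = dim_t * (
        spec.within_species_sd ** 2
        + spec.genus_offset_sd ** 2 * (1 - _sum_sq_weights(spec, lambda t: t.genus))
        + spec.subgenus_offset_sd ** 2
        * (1 - _sum_sq_weights(spec, lambda t: (t.genus, t.subgenus)))
        + spec.species_offset_sd ** 2
        * (1 - _sum_sq_weights(spec, lambda t: t.species))
    )
    var_z = expected_size_log_variance(spec)
    return math.sqrt(f / (1.0 - f) * v_rest / var_z)


def generate(spec: GeneratorSpec, template: np.ndarray | None = None) -> ShapeDataset:
    """Generate a labelled synthetic dataset (deterministic given ``spec.seed``)."""
    if template is None:
        template = TEMPLATE_WING
    template = np.asarray(template, float)
    k = template.shape[0]
    if len(np.unique(template, axis=0)) < k:
        raise ValueError("degenerate template: coincident landmarks")
    centred = template - template.mean(axis=0)
    centred /= np.sqrt((centred ** 2).sum())
    tflat = centred.reshape(-1)
    proj = _similarity_projector(tflat, k)

    rng = np.random.default_rng(spec.seed)

    genera = list(dict.fromkeys(t.genus for t in spec.taxa))
    subgenera = list(dict.fromkeys((t.genus, t.subgenus) for t in spec.taxa))
    genus_off = {g: proj @ rng.normal(0.0, spec.genus_offset_sd, 2 * k) for g in genera}
    sub_off = {s: proj @ rng.normal(0.0, spec.subgenus_offset_sd, 2 * k)
               for s in subgenera}
    sp_off = {t.species: proj @ rng.normal(0.0, spec.species_offset_sd, 2 * k)
              for t in spec.taxa}

    b_dir = proj @ rng.normal(0.0, 1.0, 2 * k)
    b_dir /= np.linalg.norm(b_dir)
    beta = allometric_magnitude(spec, k)
    mean_log = spec.mean_log_size + _log_uniform_mean(*spec.scale_range)

    rot_range = math.radians(spec.rotation_range_deg)
    configs = []
    for taxon in spec.taxa:
        base = (tflat + genus_off[taxon.genus]
                + sub_off[(taxon.genus, taxon.subgenus)] + sp_off[taxon.species])
        for i in range(taxon.n):
            log_size = (spec.mean_log_size
                        + rng.normal(0.0, spec.log_size_sd)
                        + math.log(rng.uniform(*spec.scale_range)))
            z = log_size - mean_log
            flat = base + beta * z * b_dir + rng.normal(0.0, spec.within_species_sd, 2 * k)
            shape = flat.reshape(k, 2)
            shape = shape - shape.mean(axis=0)
            shape /= np.sqrt((shape ** 2).sum())      # unit centroid size
            theta = rng.uniform(-rot_range, rot_range)
            c, s = math.cos(theta), math.sin(theta)
            rot = np.array([[c, -s], [s, c]])
            coords = math.exp(log_size) * shape @ rot.T
            coords += rng.uniform(-spec.translation_range, spec.translation_range, 2)
            configs.append(LandmarkConfiguration(
                specimen_id=f"{taxon.species}_{i + 1:03d}",
                coords=coords,
                labels={"genus": taxon.genus, "subgenus": taxon.subgenus,
                        "species": taxon.species, "site": "synthetic"},
            ))
    return ShapeDataset(configs)


def make_additive_distance_tree_fixture():
    """A 5-taxon additive distance matrix and the tree that generated it.

    Neighbor joining is consistent on additive matrices, so the generating
    topology and branch lengths are recovered exactly; used as an oracle for
    the tree module.

    Returns
    -------
    (dist, taxa, tree) : ((5, 5) ndarray, list of str, dendropy.Tree)
    """
    newick = "((A:2.0,B:3.0):1.0,(C:1.5,D:2.5):1.2,E:4.0);"
    taxa = ["A", "B", "C", "D", "E"]
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    ns = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pdm.patristic_distance(ns[taxa[i]], ns[taxa[j]])
    return dist, taxa, tree
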