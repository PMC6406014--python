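"""Synthetic field data with the statistical structure the analysis assumes.

Generates (a) the sampling manifest of the study design — 88 frogs from 16
populations of four taxon labels across central-eastern Madagascar, two of
which lack usable photographs; (b) calibrated-style photographs with a gray
standard, cluster-dependent dorsal color and injected pattern spots; (c)
RAD-style reads (inline barcode + SbfI cut-site remnant + locus sequence)
with Poisson coverage, base errors, optional exact PCR duplicates and
paralogous locus pairs; and (d) per-site read-count pileups drawn from a
Balding-Nichols admixture model.  Every generator is a pure function of the
scenario seed, and each returns truth tables so downstream estimates can be
checked against the values that produced the data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "POPULATIONS",
    "CUT_SITE_REMNANT",
    "SimScenario",
    "FrogImage",
    "ReadSimTruth",
    "PileupResult",
    "make_manifest_fixture",
    "generate_barcodes",
    "simulate_frog_image",
    "simulate_reads",
    "simulate_pileup",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

CUT_SITE_REMNANT = "TGCAGG"  # SbfI sticky-end remnant expected at read start

# Study design: (population, taxon, n_individuals, first_field_number,
# cluster ancestry proportions (A, B, C), latitude, longitude).
# Individuals are distributed evenly over each taxon's populations; field
# numbering starts at 1 except where historical ids (ABNK09, RAN11) fix an
# offset.  Cluster A holds the two outlying "green crocea" populations,
# cluster B the remaining crocea plus both aurantiaca populations, cluster
# C all milotympanum; cf. milotympanum populations are admixed between B
# and C.  Coordinates are plausible central-eastern Madagascar localities
# arranged so that within-cluster geographic and genetic distances covary.
POPULATIONS = (
    ("ABNK", "crocea", 6, 4, (1.00, 0.00, 0.00), -18.58, 48.04),
    ("VOHI", "crocea", 6, 1, (1.00, 0.00, 0.00), -19.42, 48.46),
    ("AMBA", "crocea", 6, 1, (0.00, 1.00, 0.00), -18.93, 48.20),
    ("MORA", "crocea", 6, 1, (0.00, 1.00, 0.00), -18.97, 48.24),
    ("SAHA", "crocea", 5, 1, (0.00, 1.00, 0.00), -19.00, 48.21),
    ("ANDR", "crocea", 5, 1, (0.00, 1.00, 0.00), -19.08, 48.33),
    ("TORO", "aurantiaca", 6, 1, (0.00, 1.00, 0.00), -18.87, 48.34),
    ("ANBO", "aurantiaca", 5, 1, (0.00, 1.00, 0.00), -18.90, 48.40),
    ("MILO", "milotympanum", 7, 1, (0.00, 0.00, 1.00), -18.78, 48.10),
    ("FIER", "milotympanum", 6, 1, (0.00, 0.00, 1.00), -18.80, 48.16),
    ("ANOS", "milotympanum", 6, 1, (0.00, 0.00, 1.00), -18.84, 48.13),
    ("RAN", "cf_milotympanum", 5, 7, (0.00, 0.30, 0.70), -18.81, 48.21),
    ("SABO", "cf_milotympanum", 5, 1, (0.00, 0.40, 0.60), -18.85, 48.24),
    ("AMPI", "cf_milotympanum", 5, 1, (0.00, 0.35, 0.65), -18.88, 48.18),
    ("FARA", "cf_milotympanum", 5, 1, (0.00, 0.25, 0.75), -18.83, 48.27),
    ("BEMA", "cf_milotympanum", 4, 1, (0.00, 0.45, 0.55), -18.90, 48.28),
)

_EXCLUDED_PHOTOS = ("ABNK09", "RAN11")

# Cluster mean dorsal reflectance (R, G, B): A green, B orange, C red.
_CLUSTER_COLORS = np.array(
    [
        [0.18, 0.42, 0.08],
        [0.55, 0.28, 0.05],
        [0.60, 0.14, 0.06],
    ]
)


def make_manifest_fixture() -> pd.DataFrame:
    """The fixed sampling manifest of the study design.

    88 individuals in 16 populations: 11 aurantiaca (2 populations), 34
    crocea (6), 19 milotympanum (3), 24 cf. milotympanum (5).  Exactly two
    individuals (ABNK09 and RAN11) are flagged ``photo_ok=False`` because
    their photographs are unusable; the photographed set comprises 58
    males, 26 females and 2 juveniles.  Deterministic: no randomness.
    """
    rows = []
    for pop, taxon, n, start, q, lat, lon in POPULATIONS:
        for i in range(n):
            ind = f"{pop}{start + i:02d}"
            rows.append(
                {
                    "individual_id": ind,
                    "population_id": pop,
                    "taxon_label": taxon,
                    "latitude": lat + 0.001 * i,  # individuals cluster at the site
                    "longitude": lon + 0.001 * i,
                    "photo_ok": ind not in _EXCLUDED_PHOTOS,
                }
            )
    df = pd.DataFrame(rows)
    # Sex composition of the photographed sample: 58 M, 26 F, 2 juveniles
    # (the two excluded individuals are an adult pair, M and F).
    photographed = 2 * ["juvenile"] + 26 * ["F"] + 58 * ["M"]
    sexes = []
    for ok in df.photo_ok:
        if not ok:
            sexes.append("M" if _EXCLUDED_PHOTOS[0] not in sexes else "F")
        else:
            sexes.append(photographed.pop())
    # interleave deterministically so sexes are spread across populations
    df["sex"] = sexes
    mixed = df[df.photo_ok].index.tolist()
    order = sorted(range(len(mixed)), key=lambda i: (i * 37) % 86)
    vals = df.loc[mixed, "sex"].tolist()
    df.loc[[mixed[i] for i in order], "sex"] = vals
    excl = df.individual_id.isin(_EXCLUDED_PHOTOS)
    df.loc[excl, "sex"] = ["M", "F"]
    assert len(df) == 88 and df.population_id.nunique() == 16
    assert (~df.photo_ok).sum() == 2
    return df


@dataclass(frozen=True)
class SimScenario:
    """All knobs of the synthetic study, fully determined by ``seed``.

    Defaults mirror the study conditions: three ancestral clusters with
    admixed populations, Balding-Nichols divergence at F_ST 0.2, mean
    coverage 5.4x inside the observed 1.8-13.9x range, and base error 1%.
    ``phenotype_coupling`` interpolates between cluster-independent color
    (0) and fully cluster-determined color (1).
    """

    manifest: pd.DataFrame = field(default_factory=make_manifest_fixture)
    k_true: int = 3
    divergence_fst: float = 0.2
    n_sites: int = 1000
    n_loci: int = 60
    locus_length: int = 100
    mean_coverage: float = 5.4
    coverage_range: tuple = (1.8, 13.9)
    error_rate: float = 0.01
    duplicate_rate: float = 0.0
    paralog_rate: float = 0.0
    # Paralog copies diverged 7%: distinct clusters at the 95% within-
    # individual clustering threshold, but caught by 90% self-matching.
    paralog_identity: float = 0.93
    cut_site: str = CUT_SITE_REMNANT
    barcode_length: int = 8
    trim_max: int = 8  # reads lose 0..trim_max 3' bases (quality-trimming variation)
    phenotype_coupling: float = 1.0
    color_noise_sd: float = 0.02
    spot_diameter_px: int = 8
    spot_diameter_sd: float = 0.0
    image_size: tuple = (192, 192)
    px_per_mm: float = 19.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.divergence_fst < 1:
            raise ValueError("divergence_fst must lie in (0, 1)")
        if not 0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")
        lo, hi = self.coverage_range
        if not lo <= self.mean_coverage <= hi:
            raise ValueError("mean_coverage outside coverage_range")
        for pop, q in self.population_q().items():
            if abs(sum(q) - 1.0) > 1e-9:
                raise ValueError(f"ancestry proportions for {pop} do not sum to 1")

    def population_q(self) -> dict:
        """Per-population ancestry proportions, truncated to ``k_true`` clusters."""
        out = {}
        for pop, _, _, _, q, _, _ in POPULATIONS:
            if pop in set(self.manifest.population_id):
                v = np.asarray(q[: self.k_true], dtype=float)
                total = v.sum()
                out[pop] = v / total if total > 0 else np.full(self.k_true, 1 / self.k_true)
        return out

    def q_true_matrix(self) -> np.ndarray:
        """Individual-level ancestry matrix aligned with the manifest order."""
        qpop = self.population_q()
        return np.array([qpop[p] for p in self.manifest.population_id])

    def individual_coverage(self) -> np.ndarray:
        """Per-individual mean depths: gamma-distributed, clipped to the observed range."""
        rng = np.random.default_rng([self.seed, 0xC0FFEE])
        lam = rng.gamma(shape=4.0, scale=self.mean_coverage / 4.0, size=len(self.manifest))
        lam = np.clip(lam, *self.coverage_range)
        lam = lam * (self.mean_coverage / lam.mean())
        return np.clip(lam, *self.coverage_range)

    def rng(self, *stream) -> np.random.Generator:
        keys = [self.seed] + [
            zlib.crc32(s.encode()) if isinstance(s, str) else int(s) for s in stream
        ]
        return np.random.default_rng(keys)


def balanced_cluster_subset(scenario: SimScenario, per_cluster: int = 12) -> list:
    """Ids of ``per_cluster`` unadmixed individuals from each ancestral cluster.

    Selects individuals whose population ancestry is wholly from one
    cluster, in manifest order — the balanced multi-deme design under
    which second-order rate-of-change model choice is well behaved.
    """
    q = scenario.q_true_matrix()
    per: dict[int, list] = {k: [] for k in range(scenario.k_true)}
    for ind, qi in zip(scenario.manifest.individual_id, q):
        if qi.max() == 1.0:
            per[int(qi.argmax())].append(ind)
    short = [k for k, v in per.items() if len(v) < per_cluster]
    if short:
        raise ValueError(f"clusters {short} have fewer than {per_cluster} unadmixed individuals")
    return sum((v[:per_cluster] for v in per.values()), [])


@dataclass
class FrogImage:
    """A raw (uncalibrated) synthetic photograph plus ground truth."""

    raw: np.ndarray
    roi_masks: dict
    gray_patch: tuple  # (row0, row1, col0, col1)
    px_per_mm: float
    illumination: float
    true_base_rgb: np.ndarray


def simulate_frog_image(
    scenario: SimScenario, individual_id: str, illumination: float | None = None
) -> FrogImage:
    """Render one individual's photograph with known calibration truth.

    The frame holds an 18%-reflectance gray patch (scaled by the unknown
    illumination factor the calibration must remove), a body region whose
    base color is the ancestry-weighted mixture of cluster colors (degree
    set by ``phenotype_coupling``) plus individual noise, and dark circular
    spots of the configured diameter on the side and ventral regions.
    Deterministic given the scenario seed and individual id.
    """
    mf = scenario.manifest
    row = mf[mf.individual_id == individual_id]
    if row.empty:
        raise KeyError(f"{individual_id} not in manifest")
    h, w = scenario.image_size
    d = int(round(scenario.spot_diameter_px))
    if d >= min(h, w):
        raise ValueError("spot diameter must be smaller than the image")
    rng = scenario.rng("image", individual_id)
    if illumination is None:
        illumination = float(rng.uniform(0.6, 1.1))

    q = scenario.q_true_matrix()[row.index[0]]
    cluster_color = q @ _CLUSTER_COLORS[: scenario.k_true]
    neutral = _CLUSTER_COLORS[: scenario.k_true].mean(axis=0)
    base = scenario.phenotype_coupling * cluster_color + (1 - scenario.phenotype_coupling) * neutral
    base = np.clip(base + rng.normal(0, scenario.color_noise_sd, size=3), 0.01, 0.95)

    reflectance = np.full((h, w, 3), 0.85)  # white paper background
    masks = {
        "dorsal_square": np.zeros((h, w), dtype=bool),
        "dorsal_rect": np.zeros((h, w), dtype=bool),
        "side": np.zeros((h, w), dtype=bool),
        "ventral": np.zeros((h, w), dtype=bool),
    }
    # Body: central rectangle split into dorsal (top), side (middle), ventral (bottom).
    top, bottom, left, right = h // 5, h - h // 8, w // 5, w - w // 5
    reflectance[top:bottom, left:right] = base
    third = (bottom - top) // 3
    sq = max(4, int(3 * scenario.px_per_mm) // 4)
    masks["dorsal_square"][top + 4 : top + 4 + sq, left + 4 : left + 4 + sq] = True
    masks["dorsal_rect"][top + 4 : top + 4 + sq // 3, right - 4 - sq : right - 4] = True
    masks["side"][top + third : top + 2 * third, left:right] = True
    masks["ventral"][top + 2 * third : bottom, left:right] = True

    if d > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        for surface in ("side", "ventral"):
            region = masks[surface]
            ys, xs = np.nonzero(region)
            area = region.sum()
            n_spots = max(1, int(area / (4.0 * d * d)))
            for _ in range(n_spots):
                k = rng.integers(len(ys))
                cy, cx = ys[k], xs[k]
                diam = d
                if scenario.spot_diameter_sd > 0:
                    diam = max(2, rng.normal(d, scenario.spot_diameter_sd))
                spot = (yy - cy) ** 2 + (xx - cx) ** 2 <= (diam / 2.0) ** 2
                reflectance[spot & region] = [0.04, 0.04, 0.04]

    # Gray standard patch (18% reflectance) in the top-left corner.
    g0, g1 = 4, 4 + max(8, h // 12)
    reflectance[g0:g1, g0:g1] = 0.18
    raw = reflectance * illumination
    return FrogImage(
        raw=raw,
        roi_masks=masks,
        gray_patch=(g0, g1, g0, g1),
        px_per_mm=scenario.px_per_mm,
        illumination=illumination,
        true_base_rgb=base,
    )


def generate_barcodes(n: int, length: int = 8, min_distance: int = 3, seed: int = 20140131) -> list:
    """Deterministic set of DNA barcodes with pairwise Hamming distance >= 3.

    Minimum distance 3 makes one-mismatch demultiplexing unambiguous.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    codes: list[str] = []
    attempts = 0
    while len(codes) < n:
        cand = "".join(bases[rng.integers(0, 4, size=length)])
        if all(_hamming(cand, c) >= min_distance for c in codes):
            codes.append(cand)
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("could not construct barcode set; reduce n or min_distance")
    return codes


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass
class ReadSimTruth:
    """Ground truth accompanying a simulated read set."""

    loci: list  # locus sequences (no barcode/cut site)
    snp_positions: np.ndarray
    snp_alleles: list  # (major, minor) per locus
    genotypes: np.ndarray  # minor-allele copies, (n_individuals, n_loci)
    allele_freqs: np.ndarray  # cluster x locus minor-allele frequency
    barcode_map: dict  # barcode -> individual_id
    paralog_pairs: list  # (locus_index, paralog_sequence)
    n_emitted_reads: dict  # individual -> reads emitted before duplicate injection
    n_unique_reads: dict  # individual -> distinct read sequences (dedup oracle)
    n_duplicate_reads: dict  # individual -> exact-duplicate copies appended


def _random_locus(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _mutate(rng, seq, n_changes):
    seq = list(seq)
    pos = rng.choice(len(seq), size=n_changes, replace=False)
    for p in pos:
        seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(seq)


def simulate_reads(scenario: SimScenario, individuals=None):
    """Simulate demultiplexable RAD reads for each individual.

    Each read is ``barcode + cut-site remnant + locus sequence`` carrying
    the individual's genotype-consistent allele at the locus SNP, with
    i.i.d. base errors at ``error_rate`` over the locus portion and a
    uniform 0..``trim_max`` 3' truncation emulating per-read quality
    trimming (reads of one locus therefore differ even without errors,
    so byte-identical reads are a PCR-duplicate signature).  Per-locus
    read counts are Poisson with the individual's mean depth.  Optional
    exact duplicates (``duplicate_rate`` of emitted reads) and paralogous
    locus copies at ``paralog_identity`` are injected, all recorded in the
    truth tables.

    Returns ``(reads_by_individual, truth)`` where reads are raw sequence
    strings in emission order.
    """
    if scenario.n_loci < 1:
        raise ValueError("need at least one locus")
    mf = scenario.manifest
    if individuals is None:
        individuals = list(mf.individual_id)
    rng = scenario.rng("reads")
    idx = {ind: i for i, ind in enumerate(mf.individual_id)}
    barcodes = generate_barcodes(len(individuals), length=scenario.barcode_length)
    if any(set(b) - set("ACGT") for b in barcodes):
        raise ValueError("barcode alphabet must be A/C/G/T")
    barcode_map = {bc: ind for bc, ind in zip(barcodes, individuals)}

    # Loci: random sequences (mutually dissimilar w.h.p.), one SNP each.
    loci = [_random_locus(rng, scenario.locus_length) for _ in range(scenario.n_loci)]
    snp_pos = rng.integers(10, scenario.locus_length - 10, size=scenario.n_loci)
    snp_alleles = []
    for j, seq in enumerate(loci):
        major = seq[snp_pos[j]]
        minor = rng.choice([b for b in "ACGT" if b != major])
        snp_alleles.append((major, minor))

    # Balding-Nichols cluster frequencies and admixture-weighted genotypes.
    fst = scenario.divergence_fst
    p_anc = rng.uniform(0.1, 0.9, size=scenario.n_loci)
    a, b = p_anc * (1 - fst) / fst, (1 - p_anc) * (1 - fst) / fst
    freqs = rng.beta(a, b, size=(scenario.k_true, scenario.n_loci))
    q_all = scenario.q_true_matrix()
    lam_all = scenario.individual_coverage()

    paralog_pairs = []
    n_paralogs = int(round(scenario.paralog_rate * scenario.n_loci))
    for j in rng.choice(scenario.n_loci, size=n_paralogs, replace=False):
        n_mut = max(1, int(round((1 - scenario.paralog_identity) * scenario.locus_length)))
        paralog_pairs.append((int(j), _mutate(rng, loci[j], n_mut)))

    genotypes = np.zeros((len(individuals), scenario.n_loci), dtype=int)
    reads_by_ind: dict[str, list] = {}
    n_emitted, n_unique, n_dup = {}, {}, {}
    for i, ind in enumerate(individuals):
        q = q_all[idx[ind]]
        lam = lam_all[idx[ind]]
        h = q @ freqs
        genotypes[i] = rng.binomial(2, h)
        bc = barcodes[i]
        emitted = []
        for j, seq in enumerate(loci):
            depth = rng.poisson(lam)
            for _ in range(depth):
                allele = snp_alleles[j][int(rng.random() < genotypes[i, j] / 2.0)]
                body = seq[: snp_pos[j]] + allele + seq[snp_pos[j] + 1 :]
                if scenario.error_rate > 0:
                    errs = np.nonzero(rng.random(len(body)) < scenario.error_rate)[0]
                    if len(errs):
                        body = _mutate_at(rng, body, errs)
                if scenario.trim_max > 0:
                    body = body[: len(body) - rng.integers(0, scenario.trim_max + 1)]
                emitted.append(bc + scenario.cut_site + body)
        for j, pseq in paralog_pairs:
            depth = rng.poisson(lam)
            for _ in range(depth):
                body = pseq
                if scenario.error_rate > 0:
                    errs = np.nonzero(rng.random(len(body)) < scenario.error_rate)[0]
                    if len(errs):
                        body = _mutate_at(rng, body, errs)
                if scenario.trim_max > 0:
                    body = body[: len(body) - rng.integers(0, scenario.trim_max + 1)]
                emitted.append(bc + scenario.cut_site + body)
        n_emitted[ind] = len(emitted)
        n_unique[ind] = len(set(emitted))
        n_copies = 0
        if scenario.duplicate_rate > 0 and emitted:
            # duplicates make up duplicate_rate of the final emitted pool
            n_copies = int(round(scenario.duplicate_rate / (1 - scenario.duplicate_rate) * len(emitted)))
            for k in rng.integers(0, len(emitted), size=n_copies):
                emitted.append(emitted[k])
        n_dup[ind] = n_copies
        order = rng.permutation(len(emitted))
        reads_by_ind[ind] = [emitted[k] for k in order]

    truth = ReadSimTruth(
        loci=loci,
        snp_positions=snp_pos,
        snp_alleles=snp_alleles,
        genotypes=genotypes,
        allele_freqs=freqs,
        barcode_map=barcode_map,
        paralog_pairs=paralog_pairs,
        n_emitted_reads=n_emitted,
        n_unique_reads=n_unique,
        n_duplicate_reads=n_dup,
    )
    return reads_by_ind, truth


def _mutate_at(rng, seq, positions):
    seq = list(seq)
    for p in positions:
        seq[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(seq)


@dataclass
class PileupResult:
    """Per-site biallelic read counts plus the generating truth."""

    major_counts: np.ndarray  # (n_individuals, n_sites)
    minor_counts: np.ndarray
    other_counts: np.ndarray
    genotypes: np.ndarray  # true minor-allele copies
    allele_freqs: np.ndarray  # cluster x site
    individuals: list
    populations: list
    q_true: np.ndarray

    @property
    def depth(self):
        return self.major_counts + self.minor_counts + self.other_counts


def simulate_pileup(scenario: SimScenario, individuals=None) -> PileupResult:
    """Read-count pileup drawn directly from the admixture model.

    Shortcut past read assembly: genotypes are drawn per individual per
    site under HWE at the ancestry-weighted Balding-Nichols frequencies,
    depths are Poisson at each individual's mean coverage, and individual
    read bases are flipped to another base with probability ``error_rate``
    (uniform over the three alternatives).
    """
    mf = scenario.manifest
    if individuals is None:
        individuals = list(mf.individual_id)
    idx = {ind: i for i, ind in enumerate(mf.individual_id)}
    rng = scenario.rng("pileup")
    fst = scenario.divergence_fst
    S = scenario.n_sites
    p_anc = rng.uniform(0.1, 0.9, size=S)
    a, b = p_anc * (1 - fst) / fst, (1 - p_anc) * (1 - fst) / fst
    freqs = rng.beta(a, b, size=(scenario.k_true, S))
    q_all = scenario.q_true_matrix()
    lam_all = scenario.individual_coverage()
    e = scenario.error_rate

    n = len(individuals)
    genotypes = np.zeros((n, S), dtype=int)
    major = np.zeros((n, S), dtype=int)
    minor = np.zeros((n, S), dtype=int)
    other = np.zeros((n, S), dtype=int)
    for i, ind in enumerate(individuals):
        q = q_all[idx[ind]]
        h = q @ freqs
        g = rng.binomial(2, h)
        genotypes[i] = g
        depth = rng.poisson(lam_all[idx[ind]], size=S)
        true_minor = rng.binomial(depth, g / 2.0)
        true_major = depth - true_minor
        # error channel: base kept w.p. 1-e, each alternative w.p. e/3
        maj_to_min = rng.binomial(true_major, e / 3)
        maj_to_oth = rng.binomial(true_major - maj_to_min, (2 * e / 3) / (1 - e / 3))
        min_to_maj = rng.binomial(true_minor, e / 3)
        min_to_oth = rng.binomial(true_minor - min_to_maj, (2 * e / 3) / (1 - e / 3))
        major[i] = true_major - maj_to_min - maj_to_oth + min_to_maj
        minor[i] = true_minor - min_to_maj - min_to_oth + maj_to_min
        other[i] = maj_to_oth + min_to_oth
    pops = [mf.population_id.iloc[idx[ind]] for ind in individuals]
    return PileupResult(
        major_counts=major,
        minor_counts=minor,
        other_counts=other,
        genotypes=genotypes,
        allele_freqs=freqs,
        individuals=list(individuals),
        populations=pops,
        q_true=np.array([q_all[idx[ind]] for ind in individuals]),
    )


_SCALAR_FIELDS = [
    "k_true", "divergence_fst", "n_sites", "n_loci", "locus_length", "mean_coverage",
    "error_rate", "duplicate_rate", "paralog_rate", "paralog_identity", "cut_site",
    "barcode_length", "phenotype_coupling", "color_noise_sd", "spot_diameter_px",
    "spot_diameter_sd", "px_per_mm", "seed",
]


def scenario_to_yaml(scenario: SimScenario, path):
    """Write the scenario's scalar settings as a key-value YAML config."""
    import yaml

    data = {k: getattr(scenario, k) for k in _SCALAR_FIELDS}
    data["coverage_range"] = list(scenario.coverage_range)
    data["image_size"] = list(scenario.image_size)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def scenario_from_yaml(path) -> SimScenario:
    """Load a scenario config written by :func:`scenario_to_yaml`."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    data["coverage_range"] = tuple(data.get("coverage_range", (1.8, 13.9)))
    data["image_size"] = tuple(data.get("image_size", (192, 192)))
    return SimScenario(**data)
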