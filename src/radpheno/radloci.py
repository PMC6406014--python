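"""De novo RAD locus pipeline.

Demultiplexes reads on inline barcodes, enforces the restriction cut-site
remnant, removes exact PCR duplicates, clusters each individual's reads
into markers (greedy, length-sorted, ungapped end-anchored identity — the
reads all start at the cut site, and no indels are modeled), masks
low-complexity sequence, removes within-individual paralogs by self-match,
builds a cross-individual pseudo-reference catalog, assembles per-site
allele counts by cluster membership, and applies the site filters
(biallelic, HWE heterozygote excess, coverage percentiles, presence).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "ReadRecord",
    "Marker",
    "CatalogLocus",
    "SiteTable",
    "DemuxStats",
    "demultiplex_and_cutsite_filter",
    "filter_short_reads",
    "dedup_exact",
    "cluster_within_individual",
    "mask_and_filter_markers",
    "remove_paralogs_self_match",
    "build_pseudo_reference",
    "assemble_site_table",
    "filter_sites",
    "hwe_exact_het_excess",
    "run_pipeline",
    "write_catalog_fasta",
    "write_site_table",
]

_BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class ReadRecord:
    individual_id: str
    sequence: str
    qualities: tuple | None = None


@dataclass
class Marker:
    """A per-individual (or catalog) RAD marker."""

    individual_id: str
    representative_sequence: str
    supporting_read_count: int
    member_reads: list = field(default_factory=list)
    n_fraction: float = 0.0
    masked_excess_n: bool = False
    paralog: bool = False
    in_reference: bool = False


@dataclass
class CatalogLocus:
    """A pseudo-reference locus with per-individual member markers."""

    locus_id: str
    representative_sequence: str
    members: dict  # individual_id -> list of Marker


@dataclass
class DemuxStats:
    assigned: int = 0
    unassigned_barcode: int = 0
    ambiguous_barcode: int = 0
    failed_cut_site: int = 0


@dataclass
class SiteTable:
    """Per-locus, per-site, per-individual base counts.

    ``base_counts[locus_id]`` has shape (n_individuals, locus_length, 4)
    over A/C/G/T.  Major/minor alleles and filter flags are derived from
    the counts alone.
    """

    individuals: list
    locus_ids: list
    ref_seqs: dict
    base_counts: dict

    def site_major_minor(self, locus_id: str):
        """Per-site (major_idx, minor_idx, n_alleles_observed) for one locus.

        Major and minor are the two most frequent observed bases across all
        individuals; an allele counts as observed if its pooled count is at
        least 2 and at least 10% of the site's pooled depth (noise floor
        for sequencing error).
        """
        counts = self.base_counts[locus_id].sum(axis=0)  # (L, 4)
        order = np.argsort(-counts, axis=1, kind="stable")
        major = order[:, 0]
        minor = order[:, 1]
        depth = counts.sum(axis=1)
        floor = np.maximum(2, 0.10 * depth[:, None])
        n_obs = ((counts >= floor) & (counts > 0)).sum(axis=1)
        return major, minor, n_obs


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex_and_cutsite_filter(
    reads, barcode_map: dict, cut_site: str = "TGCAGG", max_mismatch: int = 1
):
    """Assign raw reads to individuals and enforce the cut-site remnant.

    Each read must begin with a known barcode (up to ``max_mismatch``
    mismatches; barcodes must be pairwise at Hamming distance
    >= 2*max_mismatch+1 so assignment is unambiguous by construction),
    followed by the restriction cut-site remnant (again up to one
    mismatch).  Failing reads are dropped and counted, never raised.

    Returns ``(reads_by_individual, stats)`` with barcodes stripped.
    """
    barcodes = list(barcode_map)
    if len({len(b) for b in barcodes}) != 1:
        raise ValueError("all barcodes must share one length")
    need = 2 * max_mismatch + 1
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if _hamming(a, b) < need:
                raise ValueError(f"barcodes {a} and {b} closer than Hamming {need}")
    blen = len(barcodes[0])
    out: dict[str, list] = {ind: [] for ind in barcode_map.values()}
    stats = DemuxStats()
    for read in reads:
        seq = read.sequence if isinstance(read, ReadRecord) else read
        prefix = seq[:blen]
        hits = [b for b in barcodes if _hamming(prefix, b) <= max_mismatch]
        if not hits:
            stats.unassigned_barcode += 1
            continue
        if len(hits) > 1:  # unreachable with a valid barcode set; counted anyway
            stats.ambiguous_barcode += 1
            continue
        rest = seq[blen:]
        if _hamming(rest[: len(cut_site)], cut_site) > 1 or len(rest) < len(cut_site):
            stats.failed_cut_site += 1
            continue
        out[barcode_map[hits[0]]].append(rest)
        stats.assigned += 1
    return out, stats


def filter_short_reads(seqs, min_length: int = 50):
    """Drop reads shorter than ``min_length`` bp (post-trimming rule)."""
    return [s for s in seqs if len(s) >= min_length]


def dedup_exact(seqs):
    """One representative per identical sequence, first occurrence kept."""
    return list(dict.fromkeys(seqs))


def _identity(a: str, b: str) -> float:
    """Ungapped end-anchored identity: matches over the shorter length."""
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    aa = np.frombuffer(a[:n].encode(), dtype=np.uint8)
    bb = np.frombuffer(b[:n].encode(), dtype=np.uint8)
    return float((aa == bb).mean())


def cluster_within_individual(
    seqs, individual_id: str = "", identity: float = 0.95, min_reads: int = 2
):
    """Greedy length-sorted clustering of one individual's reads into markers.

    Seeds are taken longest-first (stable within equal lengths); each read
    joins the first seed whose ungapped end-anchored identity over the
    shared prefix is at least ``identity``.  Clusters with fewer than
    ``min_reads`` supporting reads are discarded; the seed sequence is the
    marker representative.
    """
    # Collapse identical sequences first: cheaper, and identical reads
    # always join the same cluster.
    counts = Counter(seqs)
    unique = list(counts)
    unique.sort(key=len, reverse=True)  # stable: first-seen order within a length
    seeds: list[str] = []
    members: list[list] = []
    for seq in unique:
        for k, seed in enumerate(seeds):
            if _identity(seq, seed) >= identity:
                members[k].append(seq)
                break
        else:
            seeds.append(seq)
            members.append([seq])
    markers = []
    for seed, mem in zip(seeds, members):
        support = sum(counts[m] for m in mem)
        if support < min_reads:
            continue
        reads = [m for m in mem for _ in range(counts[m])]
        markers.append(
            Marker(
                individual_id=individual_id,
                representative_sequence=seed,
                supporting_read_count=support,
                member_reads=reads,
            )
        )
    return markers


def mask_and_filter_markers(
    markers,
    homopolymer_min: int = 10,
    dinucleotide_min_units: int = 6,
    max_n_fraction: float = 0.30,
):
    """Mask low-complexity runs with Ns, then drop N-heavy markers.

    Homopolymer runs of >= ``homopolymer_min`` bases and dinucleotide
    repeats of >= ``dinucleotide_min_units`` units are replaced with Ns
    (a parameterized stand-in for repeat-library masking).  Markers whose
    masked sequence exceeds ``max_n_fraction`` Ns are removed; a fraction
    exactly at the threshold is retained.
    """
    homopoly = re.compile(r"(A{%d,}|C{%d,}|G{%d,}|T{%d,})" % ((homopolymer_min,) * 4))
    dinucs = [
        re.compile("(?:%s){%d,}" % (a + b, dinucleotide_min_units))
        for a in "ACGT"
        for b in "ACGT"
        if a != b
    ]
    retained = []
    for m in markers:
        seq = m.representative_sequence
        seq = homopoly.sub(lambda g: "N" * len(g.group(0)), seq)
        for pat in dinucs:
            seq = pat.sub(lambda g: "N" * len(g.group(0)), seq)
        frac = seq.count("N") / len(seq) if seq else 1.0
        m.representative_sequence = seq
        m.n_fraction = frac
        if frac > max_n_fraction:
            m.masked_excess_n = True
            continue
        retained.append(m)
    return retained


def remove_paralogs_self_match(markers, identity: float = 0.90, min_overlap: int = 50):
    """Drop markers that match another marker of the same individual.

    All-vs-all ungapped end-anchored comparison; any pair with identity
    >= ``identity`` over a shared prefix of at least ``min_overlap`` bases
    marks *both* members as paralogous (collapsed duplicated loci cannot be
    genotyped reliably), and both are removed.
    """
    n = len(markers)
    hit = np.zeros(n, dtype=bool)
    for i in range(n):
        a = markers[i].representative_sequence
        for j in range(i + 1, n):
            b = markers[j].representative_sequence
            if min(len(a), len(b)) < min_overlap:
                continue
            if _identity(a, b) >= identity:
                hit[i] = hit[j] = True
    out = []
    for flag, m in zip(hit, markers):
        if flag:
            m.paralog = True
        else:
            out.append(m)
    return out


def build_pseudo_reference(
    markers_by_individual: dict,
    identity: float = 0.90,
    min_length: int = 50,
    min_share: float = 0.60,
):
    """Cross-individual clustering of markers into a pseudo-reference catalog.

    Greedy clustering at ``identity``; a catalog locus is retained when its
    representative is at least ``min_length`` nt and its member markers
    span at least ``min_share`` of all individuals (individuals counted by
    retained markers).  The recorded membership replaces read mapping:
    downstream genotyping uses each member marker's supporting reads.
    """
    if len(markers_by_individual) < 2:
        raise ValueError("need markers from at least two individuals")
    pool = [
        (ind, m)
        for ind in markers_by_individual
        for m in markers_by_individual[ind]
    ]
    pool.sort(key=lambda t: len(t[1].representative_sequence), reverse=True)
    seeds: list[str] = []
    clusters: list[dict] = []
    for ind, m in pool:
        seq = m.representative_sequence
        for k, seed in enumerate(seeds):
            if _identity(seq, seed) >= identity:
                clusters[k].setdefault(ind, []).append(m)
                break
        else:
            seeds.append(seq)
            clusters.append({ind: [m]})
    n_ind = len(markers_by_individual)
    catalog = []
    for k, (seed, members) in enumerate(zip(seeds, clusters)):
        if len(seed) < min_length:
            continue
        if len(members) / n_ind < min_share:
            continue
        for mems in members.values():
            for m in mems:
                m.in_reference = True
        catalog.append(
            CatalogLocus(locus_id=f"locus_{len(catalog):05d}", representative_sequence=seed, members=members)
        )
    return catalog


def assemble_site_table(catalog, individuals) -> SiteTable:
    """Column-wise per-individual base counts for every catalog locus.

    Each member marker's supporting reads are compared end-anchored to the
    catalog representative; columns beyond the shared overlap are ignored.
    """
    individuals = list(individuals)
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    ref_seqs, base_counts, locus_ids = {}, {}, []
    for locus in catalog:
        L = len(locus.representative_sequence)
        counts = np.zeros((len(individuals), L, 4), dtype=np.int32)
        for ind, markers in locus.members.items():
            if ind not in ind_index:
                continue
            i = ind_index[ind]
            for m in markers:
                for read in m.member_reads:
                    n = min(len(read), L)
                    arr = np.frombuffer(read[:n].encode(), dtype=np.uint8)
                    for base, bi in _BASE_INDEX.items():
                        cols = np.nonzero(arr == ord(base))[0]
                        counts[i, cols, bi] += 1
        locus_ids.append(locus.locus_id)
        ref_seqs[locus.locus_id] = locus.representative_sequence
        base_counts[locus.locus_id] = counts
    return SiteTable(
        individuals=individuals, locus_ids=locus_ids, ref_seqs=ref_seqs, base_counts=base_counts
    )


def hwe_exact_het_excess(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """One-tailed Hardy-Weinberg exact p-value for heterozygote *excess*.

    Conditional on the observed allele counts, sums the exact probabilities
    of all heterozygote counts at least as large as observed (Levene's
    conditional distribution).  Heterozygote excess is the signature of
    collapsed paralogous loci, which is what this filter targets.
    """
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het  # copies of the rarer allele label
    log_probs = {}
    for h in range(n_het % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        hom_min = (n_minor - h) // 2
        hom_maj = n - h - hom_min
        if hom_min < 0 or hom_maj < 0:
            continue
        lp = (
            gammaln(n + 1)
            - gammaln(hom_maj + 1)
            - gammaln(h + 1)
            - gammaln(hom_min + 1)
            + h * math.log(2)
            + gammaln(n_minor + 1)
            + gammaln(2 * n - n_minor + 1)
            - gammaln(2 * n + 1)
        )
        log_probs[h] = lp
    total = np.logaddexp.reduce(list(log_probs.values()))
    tail = [lp for h, lp in log_probs.items() if h >= n_het]
    return float(min(1.0, math.exp(np.logaddexp.reduce(tail) - total)))


def _call_genotypes(major_counts, minor_counts, error_rate=0.01):
    """Naive per-individual ML genotype calls from biallelic counts."""
    e = error_rate
    nm = np.asarray(major_counts, dtype=float)
    nn = np.asarray(minor_counts, dtype=float)
    logl = np.stack(
        [
            nm * math.log(1 - e) + nn * math.log(e / 3),
            (nm + nn) * math.log(0.5 - e / 3),
            nm * math.log(e / 3) + nn * math.log(1 - e),
        ],
        axis=-1,
    )
    calls = np.argmax(logl, axis=-1)
    calls = np.where(nm + nn == 0, -1, calls)
    return calls


@dataclass
class SiteFilterResult:
    flags: pd.DataFrame  # one row per (locus, position) candidate site
    retained: pd.DataFrame  # surviving sites
    n_retained: int


def filter_sites(
    table: SiteTable,
    hwe_alpha: float = 1e-4,
    coverage_percentiles: tuple = (1, 99),
    min_depth: int = 3,
    min_presence: float = 0.60,
    error_rate: float = 0.01,
) -> SiteFilterResult:
    """Apply the site filters to variable sites of a SiteTable.

    Independent per-rule flags: (a) more than two alleles observed at any
    site drops the whole marker; (b) a one-tailed HWE exact test for
    heterozygote excess at p <= ``hwe_alpha`` drops the site; (c) a pooled
    site depth outside the [1st, 99th] percentile across sites drops the
    site; (d) sites covered at >= ``min_depth`` in fewer than
    ``min_presence`` of individuals are excluded from downstream use.
    """
    rows = []
    for locus_id in table.locus_ids:
        counts = table.base_counts[locus_id]  # (n_ind, L, 4)
        major, minor, n_obs = table.site_major_minor(locus_id)
        pooled = counts.sum(axis=0)
        L = counts.shape[1]
        variable = np.nonzero(n_obs >= 2)[0]
        marker_dropped = bool((n_obs > 2).any())
        for pos in variable:
            maj_c = counts[:, pos, major[pos]]
            min_c = counts[:, pos, minor[pos]]
            depth = counts[:, pos, :].sum(axis=1)
            calls = _call_genotypes(maj_c, min_c, error_rate)
            n_hom_major = int((calls == 0).sum())
            n_het = int((calls == 1).sum())
            n_hom_minor = int((calls == 2).sum())
            p_hwe = hwe_exact_het_excess(n_hom_major, n_het, n_hom_minor)
            rows.append(
                {
                    "locus_id": locus_id,
                    "position": int(pos),
                    "major": "ACGT"[major[pos]],
                    "minor": "ACGT"[minor[pos]],
                    "site_depth": int(pooled[pos].sum()),
                    "n_alleles": int(n_obs[pos]),
                    "flag_multiallelic_marker": marker_dropped,
                    "hwe_p": p_hwe,
                    "flag_hwe_excess": bool(p_hwe <= hwe_alpha),
                    "presence": float((depth >= min_depth).mean()),
                    "flag_low_presence": bool((depth >= min_depth).mean() < min_presence),
                }
            )
    flags = pd.DataFrame(rows)
    if flags.empty:
        return SiteFilterResult(flags=flags, retained=flags, n_retained=0)
    lo, hi = np.percentile(flags.site_depth, coverage_percentiles)
    flags["flag_coverage_percentile"] = (flags.site_depth < lo) | (flags.site_depth > hi)
    keep = ~(
        flags.flag_multiallelic_marker
        | flags.flag_hwe_excess
        | flags.flag_coverage_percentile
        | flags.flag_low_presence
    )
    retained = flags[keep].reset_index(drop=True)
    return SiteFilterResult(flags=flags, retained=retained, n_retained=len(retained))


@dataclass
class PipelineResult:
    markers_by_individual: dict
    catalog: list
    site_table: SiteTable
    site_filters: SiteFilterResult
    demux_stats: DemuxStats


def run_pipeline(
    raw_reads,
    barcode_map: dict,
    cut_site: str = "TGCAGG",
    min_read_length: int = 50,
    identity_within: float = 0.95,
    identity_across: float = 0.90,
    min_reads: int = 2,
    min_length: int = 50,
    min_share: float = 0.60,
    paralog_identity: float = 0.90,
    error_rate: float = 0.01,
    **filter_kwargs,
) -> PipelineResult:
    """Run the full de novo RAD pipeline from raw reads to filtered sites."""
    by_ind, stats = demultiplex_and_cutsite_filter(raw_reads, barcode_map, cut_site)
    markers_by_individual = {}
    for ind, seqs in by_ind.items():
        seqs = filter_short_reads(seqs, min_read_length)
        seqs = dedup_exact(seqs)
        markers = cluster_within_individual(seqs, ind, identity_within, min_reads)
        markers = mask_and_filter_markers(markers)
        markers = remove_paralogs_self_match(markers, paralog_identity, min_length)
        if markers:
            markers_by_individual[ind] = markers
    catalog = build_pseudo_reference(markers_by_individual, identity_across, min_length, min_share)
    site_table = assemble_site_table(catalog, sorted(markers_by_individual))
    site_filters = filter_sites(site_table, error_rate=error_rate, **filter_kwargs)
    return PipelineResult(markers_by_individual, catalog, site_table, site_filters, stats)


def write_catalog_fasta(catalog, path):
    """Write the pseudo-reference catalog as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(loc.representative_sequence), id=loc.locus_id, description=f"n_individuals={len(loc.members)}")
        for loc in catalog
    ]
    seqio_write(records, path, "fasta")


def write_site_table(table: SiteTable, result: SiteFilterResult, path):
    """Write retained sites as a VCF-like tab-delimited file (AD/DP per sample)."""
    with open(path, "w") as fh:
        header = ["#CHROM", "POS", "REF", "ALT"] + list(table.individuals)
        fh.write("\t".join(header) + "\n")
        for _, row in result.retained.iterrows():
            counts = table.base_counts[row.locus_id]
            maj_i = _BASE_INDEX[row.major]
            min_i = _BASE_INDEX[row.minor]
            cells = []
            for i in range(len(table.individuals)):
                ad = f"{counts[i, row.position, maj_i]},{counts[i, row.position, min_i]}"
                dp = counts[i, row.position, :].sum()
                cells.append(f"{ad}:{dp}")
            fh.write(
                "\t".join(
                    [row.locus_id, str(row.position + 1), row.major, row.minor] + cells
                )
                + "\n"
            )
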