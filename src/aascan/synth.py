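"""Synthetic cancer-cohort generator with planted ground truth.

Generates every input the pipeline consumes — reference sequence, gene
models, per-sample somatic SNV tables, harmfulness predictions, GO and
pathway gene sets, a functional-interaction network, protein-domain
intervals and a cancer-gene list — on a single linear synthetic
chromosome with non-overlapping genes.  The planted structure (driver
proteins per cancer, driver pathways, per-cancer trinucleotide spectrum
weights, and the intended coding consequence of every emitted SNV) is
written to a sidecar truth object that the pipeline never reads, so each
downstream stage has a recovery oracle.

Randomness: one master seed; each stage draws from its own substream
(``default_rng([seed, stage])``) so stages can be regenerated
independently and identical seeds give byte-identical files.

Mutational model: per sample, a Poisson number of background SNVs whose
96-channel trinucleotide class is drawn from the cancer's spectrum
weights, the genomic site being chosen uniformly among reference
positions carrying the channel's context; driver genes additionally
receive extra missense SNVs at ``driver_boost``-fold the background
missense rate of a gene of their size, channel-matched the same way.
Harmfulness probabilities come from a high Beta for driver-protein
substitutions and a low, wide Beta for the rest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from . import iofmt
from .annotate import GeneModel, annotate_catalog
from .enrich import GeneSetCollection
from .genetics import CODON_TO_AA, STOP, reverse_complement
from .harmful import classify_stub, DEFAULT_THRESHOLDS

BASE_ORDER = "ACGT"
_B = {b: i for i, b in enumerate(BASE_ORDER)}

# consequence codes used by the generator's own bookkeeping
CONSEQ_LABELS = ("noncoding", "splice_site", "synonymous", "missense", "nonsense", "stop_loss")
NONCODING, SPLICE, SYN, MIS, NON, STOPLOSS = range(6)

#: amino-acid id per codon index (codon index = 16*b0 + 4*b1 + b2, A<C<G<T)
_AA64 = np.zeros(64, dtype="<U1")
for _i in range(64):
    _codon = BASE_ORDER[_i // 16] + BASE_ORDER[(_i // 4) % 4] + BASE_ORDER[_i % 4]
    _AA64[_i] = CODON_TO_AA[_codon]

#: alt rank among the three non-ref bases, alphabetical
_RANK = np.full((4, 4), -1, dtype=np.int8)
for _r in range(4):
    for _rank, _a in enumerate(x for x in range(4) if x != _r):
        _RANK[_r, _a] = _rank

_CMAP_C = np.array([0, -1, 1, 2])  # C>A, C>G, C>T
_CMAP_T = np.array([3, 4, 5, -1])  # T>A, T>C, T>G


class ConfigError(ValueError):
    pass


def default_spectrum_weights(n_cancers: int) -> np.ndarray:
    """One biased 96-channel probability vector per cancer.

    Cancer ``c`` concentrates 60 % of its mass uniformly on the 16
    contexts of substitution class ``c mod 6`` and spreads the remaining
    40 % uniformly, giving each synthetic cancer a recognizable spectrum.
    """
    w = np.full((n_cancers, 96), 0.4 / 96)
    for c in range(n_cancers):
        cls = c % 6
        w[c, cls * 16 : (cls + 1) * 16] += 0.6 / 16
    return w


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort (defaults are the study)."""

    seed: int = 0
    n_cancers: int = 3
    samples_per_cancer: int = 60
    n_genes: int = 2000
    transcripts_per_gene: tuple[int, int] = (1, 2)
    cds_length_range: tuple[int, int] = (60, 300)  # codons incl. stop
    drivers_per_cancer: int = 8
    background_rate: float = 220.0  # expected SNVs per sample
    driver_boost: float = 20.0  # fold-enrichment of missense in drivers
    spectrum_weights: np.ndarray | None = None  # (n_cancers, 96)
    harm_high: tuple[float, float] = (50.0, 1.0)  # Beta(a, b) for driver AASs
    harm_low: tuple[float, float] = (0.2, 0.35)  # Beta(a, b) for the rest
    n_pathways: int = 15
    pathway_size: int = 8
    n_go_terms: int = 30
    network_density: float = 0.003
    within_pathway_density: float = 0.35
    class_thresholds: tuple[float, float] = DEFAULT_THRESHOLDS

    def __post_init__(self):
        def positive(name):
            if getattr(self, name) <= 0:
                raise ConfigError(f"invalid config field: {name} must be positive")

        for name in ("n_cancers", "n_genes", "n_pathways", "pathway_size", "n_go_terms"):
            positive(name)
        for name in ("samples_per_cancer", "drivers_per_cancer"):
            if getattr(self, name) < 0:
                raise ConfigError(f"invalid config field: {name} must be >= 0")
        if self.background_rate < 0:
            raise ConfigError("invalid config field: background_rate must be >= 0")
        if self.driver_boost < 1:
            raise ConfigError("invalid config field: driver_boost must be >= 1")
        lo, hi = self.transcripts_per_gene
        if not 1 <= lo <= hi:
            raise ConfigError("invalid config field: transcripts_per_gene")
        lo, hi = self.cds_length_range
        if not 10 <= lo <= hi:
            raise ConfigError("invalid config field: cds_length_range (min 10 codons)")
        if self.drivers_per_cancer >= self.n_genes:
            raise ConfigError(
                "invalid config field: drivers_per_cancer must be < n_genes"
            )
        if self.n_cancers * self.drivers_per_cancer > self.n_genes:
            raise ConfigError(
                "invalid config field: drivers_per_cancer (driver sets of all "
                "cancers must fit in n_genes disjointly)"
            )
        if self.pathway_size > self.n_genes:
            raise ConfigError("invalid config field: pathway_size exceeds n_genes")
        if not 0 <= self.network_density <= 1:
            raise ConfigError("invalid config field: network_density")
        if self.spectrum_weights is None:
            self.spectrum_weights = default_spectrum_weights(self.n_cancers)
        self.spectrum_weights = np.asarray(self.spectrum_weights, dtype=float)
        if self.spectrum_weights.shape != (self.n_cancers, 96):
            raise ConfigError("invalid config field: spectrum_weights shape")
        if np.any(np.abs(self.spectrum_weights.sum(axis=1) - 1) > 1e-9):
            raise ConfigError("invalid config field: spectrum_weights must sum to 1")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


@dataclass
class PlantedTruth:
    """Sidecar ground truth; emitted with the data, never read by stages."""

    driver_genes: dict[str, list[str]] = field(default_factory=dict)
    driver_proteins: dict[str, list[str]] = field(default_factory=dict)
    driver_pathways: dict[str, list[str]] = field(default_factory=dict)
    channel_weights_used: dict[str, list[float]] = field(default_factory=dict)
    record_consequences: list[str] = field(default_factory=list)

    def consequence_counts(self, variants: pd.DataFrame) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cancer_type": variants["cancer_type"].to_numpy(),
                "consequence": self.record_consequences,
            }
        )
        return df.groupby(["cancer_type", "consequence"]).size().unstack(fill_value=0)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass
class SyntheticGene:
    gene_id: str
    strand: str
    transcripts: list[GeneModel]

    @property
    def longest(self) -> GeneModel:
        from .annotate import select_longest_transcript

        return select_longest_transcript(self.transcripts)


class _GenomeIndex:
    """Vectorized per-position consequence/context bookkeeping."""

    def __init__(self, b: np.ndarray):
        self.b = b  # base codes, 0-based positions
        n = len(b)
        self.conseq = np.zeros((n, 3), dtype=np.uint8)  # noncoding default
        # canonical pyrimidine context code (0..31) for interior positions
        r = b[1:-1]
        fp = b[:-2]
        tp = b[2:]
        pur = (r == 0) | (r == 2)
        r2 = np.where(pur, 3 - r, r)
        fp2 = np.where(pur, 3 - tp, fp)
        tp2 = np.where(pur, 3 - fp, tp)
        pyr = (r2 == 3).astype(np.int64)  # C -> 0, T -> 1
        self.ctx32 = pyr * 16 + fp2 * 4 + tp2
        order = np.argsort(self.ctx32, kind="stable")
        starts = np.searchsorted(self.ctx32[order], np.arange(33))
        # interior genomic positions grouped by context code
        self.ctx_groups = [order[starts[i] : starts[i + 1]] + 1 for i in range(32)]

    def channel_of(self, pos: np.ndarray, alt: np.ndarray) -> np.ndarray:
        b = self.b
        r = b[pos]
        fp = b[pos - 1]
        tp = b[pos + 1]
        pur = (r == 0) | (r == 2)
        r2 = np.where(pur, 3 - r, r)
        a2 = np.where(pur, 3 - alt, alt)
        fp2 = np.where(pur, 3 - tp, fp)
        tp2 = np.where(pur, 3 - fp, tp)
        cls = np.where(r2 == 1, _CMAP_C[a2], _CMAP_T[a2])
        return cls * 16 + fp2 * 4 + tp2

    def channel_site(self, channel: int) -> tuple[int, int, np.ndarray]:
        """(pyrimidine ref code, pyrimidine alt code, candidate positions)."""
        cls, ctx = divmod(channel, 16)
        if cls < 3:
            ref, alt = 1, (0, 2, 3)[cls]  # C > A/G/T
        else:
            ref, alt = 3, (0, 1, 2)[cls - 3]  # T > A/C/G
        pyr = 0 if ref == 1 else 1
        return ref, alt, self.ctx_groups[pyr * 16 + ctx]

    def consequence_label(self, pos: int, alt_code: int) -> str:
        return CONSEQ_LABELS[self.conseq[pos, _RANK[self.b[pos], alt_code]]]


@dataclass
class GenomeBundle:
    reference: dict[str, str]
    genes: list[SyntheticGene]
    chrom: str
    index: _GenomeIndex
    # per-gene missense candidates: gene_id -> (pos0, alt_code, channel)
    missense_sites: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def models(self) -> list[GeneModel]:
        return [m for g in self.genes for m in g.transcripts]

    def gene_chrom(self) -> dict[str, str]:
        return {g.gene_id: self.chrom for g in self.genes}

    def protein_of_gene(self) -> dict[str, str]:
        return {g.gene_id: g.longest.protein_id for g in self.genes}

    def protein_lengths(self) -> pd.Series:
        return pd.Series(
            {g.longest.protein_id: g.longest.protein_length for g in self.genes}
        )


SENSE_CODONS = [c for c, aa in CODON_TO_AA.items() if aa != STOP and c != "ATG"]
STOP_CODONS = [c for c, aa in CODON_TO_AA.items() if aa == STOP]


def generate_genes(config: SyntheticConfig) -> GenomeBundle:
    """Build the synthetic chromosome and gene models.

    Genes are non-overlapping, on alternating random strands, with
    codon-aligned CDS exons (every exon a multiple of 3 nt, first codon
    ATG, final codon a stop, no internal stops by construction).  Genes
    with more than one transcript skip distinct internal exons in the
    shorter isoforms, so isoform proteins differ in length and the
    longest-transcript rule is exercised.
    """
    rng = config.rng(1)
    t_lo, t_hi = config.transcripts_per_gene
    c_lo, c_hi = config.cds_length_range

    chunks: list[str] = []
    genes: list[SyntheticGene] = []
    cursor = 0  # 0-based next free position
    gene_meta = []  # (gene_id, strand, exon intervals genomic 0-based, n_tx)

    for gi in range(config.n_genes):
        gap = int(rng.integers(40, 101))
        chunks.append("".join(BASE_ORDER[i] for i in rng.integers(0, 4, gap)))
        cursor += gap

        gene_id = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(t_lo, t_hi + 1))
        if gi == 0 and t_hi >= 2:
            n_tx = max(n_tx, 2)  # guarantee one multi-isoform gene
        n_codons = int(rng.integers(c_lo, c_hi + 1))
        n_exons = int(rng.integers(3 if n_tx > 1 else 1, 5))
        n_exons = min(n_exons, n_codons // 2)
        # split codons over exons, each exon >= 2 codons
        cuts = np.sort(rng.choice(np.arange(2, n_codons - 1, 2), n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), n_codons]
        exon_codons = [bounds[i + 1] - bounds[i] for i in range(n_exons)]

        body = ["ATG"]
        body += [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)]
        body.append(STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))])
        cds = "".join(body)

        # assemble pre-mRNA in coding order
        pre = []
        exon_coding_intervals = []  # 0-based [a, b) within pre-mRNA
        off_cds = 0
        off_pre = 0
        for k, nc in enumerate(exon_codons):
            ex = cds[off_cds : off_cds + 3 * nc]
            pre.append(ex)
            exon_coding_intervals.append((off_pre, off_pre + len(ex)))
            off_cds += 3 * nc
            off_pre += len(ex)
            if k < n_exons - 1:
                intron_len = int(rng.integers(30, 81))
                intron = "".join(BASE_ORDER[i] for i in rng.integers(0, 4, intron_len))
                pre.append(intron)
                off_pre += intron_len
        pre_mrna = "".join(pre)

        if strand == "+":
            segment = pre_mrna
            exon_genomic = [
                (cursor + a, cursor + b - 1) for a, b in exon_coding_intervals
            ]
        else:
            segment = reverse_complement(pre_mrna)
            L = len(pre_mrna)
            exon_genomic = [
                (cursor + L - b, cursor + L - 1 - a) for a, b in exon_coding_intervals
            ]
            exon_genomic.reverse()  # genomic-start order
        chunks.append(segment)
        cursor += len(segment)

        # transcripts: full model first, then isoforms skipping internal exons
        n_ex = len(exon_genomic)
        exon_1based = tuple((s + 1, e + 1) for s, e in exon_genomic)
        transcripts = [
            GeneModel(gene_id, f"T{gi:04d}.1", strand, exon_1based)
        ]
        internal = [int(x) for x in rng.permutation(np.arange(1, n_ex - 1))]
        for j in range(1, min(n_tx, 1 + len(internal))):
            skip = internal[j - 1]
            exons = tuple(iv for i, iv in enumerate(exon_1based) if i != skip)
            transcripts.append(GeneModel(gene_id, f"T{gi:04d}.{j + 1}", strand, exons))
        genes.append(SyntheticGene(gene_id, strand, transcripts))
        gene_meta.append((gene_id, strand, exon_genomic))

    chunks.append("".join(BASE_ORDER[i] for i in rng.integers(0, 4, 60)))
    genome = "".join(chunks)
    b = np.frombuffer(genome.encode(), dtype=np.uint8)
    codes = np.full(256, -1, dtype=np.int8)
    for base, i in _B.items():
        codes[ord(base)] = i
    b = codes[b].astype(np.int64)

    index = _GenomeIndex(b)
    missense_sites: dict[str, tuple] = {}
    for gene_id, strand, exon_genomic in gene_meta:
        _fill_consequences(index, gene_id, strand, exon_genomic, missense_sites)

    return GenomeBundle(
        reference={"chr1": genome},
        genes=genes,
        chrom="chr1",
        index=index,
        missense_sites=missense_sites,
    )


def _fill_consequences(index, gene_id, strand, exon_genomic, missense_sites):
    """Vectorized consequence labels for the longest transcript of one gene."""
    b = index.b
    minus = strand == "-"
    pos = np.concatenate(
        [np.arange(s, e + 1) for s, e in exon_genomic]
    )
    if minus:
        pos_coding = pos[::-1]
        c = 3 - b[pos_coding]
    else:
        pos_coding = pos
        c = b[pos_coding]
    cods = c.reshape(-1, 3)
    cod_idx = cods[:, 0] * 16 + cods[:, 1] * 4 + cods[:, 2]
    ref_aa = _AA64[cod_idx]
    n_cod = len(cod_idx)
    mis_pos, mis_alt, conseq_arr = [], [], None
    for off in range(3):
        p_cod = pos_coding[off::3]  # genomic pos of this codon slot
        c_off = cods[:, off]
        weight = 4 ** (2 - off)
        for a in range(4):
            valid = c_off != a
            if not valid.any():
                continue
            alt_idx = cod_idx + (a - c_off) * weight
            alt_aa = _AA64[alt_idx]
            out = np.full(n_cod, MIS, dtype=np.uint8)
            out[alt_aa == ref_aa] = SYN
            out[(alt_aa == STOP) & (ref_aa != STOP)] = NON
            out[(ref_aa == STOP) & (alt_aa != STOP)] = STOPLOSS
            # plus-strand alt base for storage
            plus_alt = (3 - a) if minus else a
            gpos = p_cod[valid]
            plus_ref = b[gpos]
            index.conseq[gpos, _RANK[plus_ref, plus_alt]] = out[valid]
            mmask = valid & (out == MIS)
            if mmask.any():
                mis_pos.append(p_cod[mmask])
                mis_alt.append(np.full(int(mmask.sum()), plus_alt))
    # splice flags: first/last 2 nt of each intron
    for (s1, e1), (s2, e2) in zip(exon_genomic, exon_genomic[1:]):
        for p in (e1 + 1, e1 + 2, s2 - 2, s2 - 1):
            if e1 < p < s2:
                index.conseq[p, :] = SPLICE
    if mis_pos:
        mp = np.concatenate(mis_pos)
        ma = np.concatenate(mis_alt)
        interior = (mp > 0) & (mp < len(b) - 1)
        mp, ma = mp[interior], ma[interior]
        missense_sites[gene_id] = (mp, ma, index.channel_of(mp, ma))


def generate_cohort(
    config: SyntheticConfig, genome: GenomeBundle
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Per-sample SNV tables with planted drivers and spectrum biases.

    Returns the variant table (sample_id, cancer_type, chrom, pos, ref,
    alt; 1-based positions) and the sidecar truth.
    """
    if not genome.genes:
        raise ConfigError("empty gene set")
    rng = config.rng(2)
    index = genome.index
    b = index.b
    genome_len = len(b)
    truth = PlantedTruth()

    perm = rng.permutation(len(genome.genes))
    prot_of = genome.protein_of_gene()

    rows: list[tuple] = []
    labels: list[str] = []
    for ci in range(config.n_cancers):
        cancer = f"cancer{ci:02d}"
        weights = config.spectrum_weights[ci]
        truth.channel_weights_used[cancer] = [float(x) for x in weights]
        d = config.drivers_per_cancer
        driver_idx = perm[ci * d : (ci + 1) * d]
        driver_genes = sorted(genome.genes[i].gene_id for i in driver_idx)
        truth.driver_genes[cancer] = driver_genes
        truth.driver_proteins[cancer] = sorted(prot_of[g] for g in driver_genes)

        # per-driver extra-missense rates (boost - 1 extra fold); sites are
        # grouped by channel so the channel marginal follows the weights
        driver_lam = {}
        driver_channels = {}
        for g in driver_genes:
            if g not in genome.missense_sites:
                continue
            mp, ma, mch = genome.missense_sites[g]
            driver_lam[g] = (
                (config.driver_boost - 1.0)
                * config.background_rate
                * len(mp)
                / (3.0 * genome_len)
            )
            uniq, inv = np.unique(mch, return_inverse=True)
            site_groups = [np.nonzero(inv == u)[0] for u in range(len(uniq))]
            w = weights[uniq]
            s = w.sum()
            driver_channels[g] = (mp, ma, site_groups, w / s if s > 0 else None)

        for si in range(config.samples_per_cancer):
            sample = f"{cancer}_S{si:03d}"
            seen: set[int] = set()
            # background, channel-sampled
            n_bg = int(rng.poisson(config.background_rate))
            if n_bg:
                ch_counts = np.bincount(
                    rng.choice(96, size=n_bg, p=weights), minlength=96
                )
                for ch in np.nonzero(ch_counts)[0]:
                    ref_pyr, alt_pyr, sites = index.channel_site(int(ch))
                    if len(sites) == 0:
                        continue
                    picks = rng.choice(sites, size=int(ch_counts[ch]))
                    for p in np.atleast_1d(picks):
                        p = int(p)
                        if p in seen:
                            continue
                        seen.add(p)
                        ref_code = int(b[p])
                        alt_code = alt_pyr if ref_code == ref_pyr else 3 - alt_pyr
                        rows.append(
                            (
                                sample,
                                cancer,
                                genome.chrom,
                                p + 1,
                                BASE_ORDER[ref_code],
                                BASE_ORDER[alt_code],
                            )
                        )
                        labels.append(index.consequence_label(p, alt_code))
            # planted driver missense, channel-matched
            for g in driver_genes:
                lam = driver_lam.get(g, 0.0)
                if lam <= 0:
                    continue
                k = int(rng.poisson(lam))
                if k == 0:
                    continue
                mp, ma, site_groups, w = driver_channels[g]
                if w is None:
                    picks = rng.integers(0, len(mp), size=k)
                else:
                    chans = rng.choice(len(site_groups), size=k, p=w)
                    picks = [
                        int(rng.choice(site_groups[ch])) for ch in np.atleast_1d(chans)
                    ]
                for j in np.atleast_1d(picks):
                    p = int(mp[j])
                    if p in seen:
                        continue
                    seen.add(p)
                    alt_code = int(ma[j])
                    rows.append(
                        (
                            sample,
                            cancer,
                            genome.chrom,
                            p + 1,
                            BASE_ORDER[int(b[p])],
                            BASE_ORDER[alt_code],
                        )
                    )
                    labels.append(index.consequence_label(p, alt_code))

    variants = pd.DataFrame(
        rows, columns=["sample_id", "cancer_type", "chrom", "pos", "ref", "alt"]
    )
    truth.record_consequences = labels
    return variants, truth


def generate_predictions(
    aas: pd.DataFrame, truth: PlantedTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Harmfulness predictions for every unique missense substitution.

    Driver-protein substitutions draw their probability from the
    ``harm_high`` Beta, all others from ``harm_low``; three-way classes
    follow the probability-threshold rule.
    """
    rng = config.rng(3)
    missense = aas[aas["consequence"] == "missense"]
    keys = missense.drop_duplicates(
        subset=["protein_id", "residue_pos", "ref_aa", "alt_aa"]
    )[["protein_id", "residue_pos", "ref_aa", "alt_aa"]].reset_index(drop=True)
    drivers = set().union(*truth.driver_proteins.values()) if truth.driver_proteins else set()
    is_driver = keys["protein_id"].isin(drivers).to_numpy()
    prob = np.empty(len(keys))
    a, b_ = config.harm_high
    prob[is_driver] = rng.beta(a, b_, size=int(is_driver.sum()))
    a, b_ = config.harm_low
    prob[~is_driver] = rng.beta(a, b_, size=int((~is_driver).sum()))
    out = keys.copy()
    out["probability"] = prob
    out["class"] = [classify_stub(p, config.class_thresholds) for p in prob]
    return out


def generate_genesets_and_network(
    genome: GenomeBundle, truth: PlantedTruth, config: SyntheticConfig
) -> tuple[GeneSetCollection, GeneSetCollection, nx.Graph]:
    """GO terms, pathways (with planted driver pathways) and the network.

    Each cancer's driver genes are chunked into planted pathways of
    ``pathway_size`` (padded with random non-driver genes); the remaining
    pathways and all GO terms are random gene sets.  The interaction
    network connects same-pathway genes densely
    (``within_pathway_density``) on top of sparse background edges
    (``network_density``), so planted pathways double as planted modules.
    """
    rng = config.rng(4)
    gene_ids = [g.gene_id for g in genome.genes]
    all_drivers = set().union(*truth.driver_genes.values()) if truth.driver_genes else set()
    non_drivers = [g for g in gene_ids if g not in all_drivers]

    pathways: dict[str, frozenset[str]] = {}
    for cancer in sorted(truth.driver_genes):
        drivers = list(truth.driver_genes[cancer])
        planted = []
        for pi in range(0, len(drivers), config.pathway_size):
            chunk = drivers[pi : pi + config.pathway_size]
            if len(chunk) < config.pathway_size:
                pad = rng.choice(
                    non_drivers, config.pathway_size - len(chunk), replace=False
                )
                chunk = chunk + [str(x) for x in pad]
            name = f"PW_{cancer}_{pi // config.pathway_size:02d}"
            pathways[name] = frozenset(chunk)
            planted.append(name)
        truth.driver_pathways[cancer] = planted
    ri = 0
    while len(pathways) < config.n_pathways:
        members = rng.choice(gene_ids, config.pathway_size, replace=False)
        pathways[f"PW_rand_{ri:03d}"] = frozenset(str(x) for x in members)
        ri += 1

    go_terms = {}
    for ti in range(config.n_go_terms):
        size = int(rng.integers(5, min(51, config.n_genes + 1)))
        members = rng.choice(gene_ids, size, replace=False)
        go_terms[f"GO:{ti:07d}"] = frozenset(str(x) for x in members)

    universe = frozenset(gene_ids)
    go = GeneSetCollection(sets=go_terms, universe=universe)
    pw = GeneSetCollection(sets=pathways, universe=universe)

    g = nx.Graph()
    g.add_nodes_from(gene_ids)
    n = len(gene_ids)
    n_pairs = n * (n - 1) // 2
    k = int(rng.binomial(n_pairs, config.network_density))
    if k:
        # background edges: sample random pairs, drop self/duplicates
        i = rng.integers(0, n, size=2 * k + 10)
        j = rng.integers(0, n, size=2 * k + 10)
        added = 0
        for a, bb in zip(i, j):
            if added >= k:
                break
            if a == bb:
                continue
            u, v = gene_ids[int(a)], gene_ids[int(bb)]
            if not g.has_edge(u, v):
                g.add_edge(u, v)
                added += 1
    for members in pathways.values():
        members = sorted(members)
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                if rng.random() < config.within_pathway_density:
                    g.add_edge(members[x], members[y])
    return go, pw, g


def generate_domains(
    genome: GenomeBundle, truth: PlantedTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Protein-domain interval table with a planted driver-hotspot domain.

    Every driver protein carries one instance of accession IPR99999
    spanning its central half; other proteins draw 0-2 instances from a
    pool of generic accessions at random positions.
    """
    rng = config.rng(5)
    drivers = set().union(*truth.driver_proteins.values()) if truth.driver_proteins else set()
    pool = [f"IPR{10000 + i:05d}" for i in range(40)]
    rows = []
    for gene in genome.genes:
        model = gene.longest
        plen = model.protein_length
        if model.protein_id in drivers and plen >= 8:
            start = plen // 4 + 1
            rows.append(
                (model.protein_id, "IPR99999", "planted_hotspot_domain", start, start + plen // 2)
            )
        for _ in range(int(rng.integers(0, 3))):
            if plen < 10:
                continue
            dlen = int(rng.integers(8, max(9, plen // 2)))
            start = int(rng.integers(1, plen - dlen + 2))
            acc = pool[int(rng.integers(0, len(pool)))]
            rows.append((model.protein_id, acc, acc.lower(), start, start + dlen - 1))
    return pd.DataFrame(rows, columns=["protein_id", "accession", "name", "start", "end"])


def generate_cancer_gene_list(
    genome: GenomeBundle, truth: PlantedTruth, config: SyntheticConfig, n_extra: int = 10
) -> list[str]:
    """Census-style known-cancer-gene list: all planted drivers + extras."""
    rng = config.rng(6)
    drivers = sorted(set().union(*truth.driver_genes.values())) if truth.driver_genes else []
    others = [g.gene_id for g in genome.genes if g.gene_id not in set(drivers)]
    extra = [str(x) for x in rng.choice(others, min(n_extra, len(others)), replace=False)]
    return sorted(set(drivers) | set(extra))


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeBundle
    variants: pd.DataFrame
    truth: PlantedTruth
    aas: pd.DataFrame
    summary: object
    predictions: pd.DataFrame
    go: GeneSetCollection
    pathways: GeneSetCollection
    network: nx.Graph
    domains: pd.DataFrame
    cancer_genes: list[str]


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Run every generator stage; annotation is applied to produce the
    AAS table that the prediction file is keyed on (as the external
    predictor would be run on annotated substitutions)."""
    genome = generate_genes(config)
    variants, truth = generate_cohort(config, genome)
    aas, summary = annotate_catalog(
        variants, genome.models(), genome.reference, genome.gene_chrom()
    )
    predictions = generate_predictions(aas, truth, config)
    go, pathways, network = generate_genesets_and_network(genome, truth, config)
    domains = generate_domains(genome, truth, config)
    cancer_genes = generate_cancer_gene_list(genome, truth, config)
    return SyntheticDataset(
        config=config,
        genome=genome,
        variants=variants,
        truth=truth,
        aas=aas,
        summary=summary,
        predictions=predictions,
        go=go,
        pathways=pathways,
        network=network,
        domains=domains,
        cancer_genes=cancer_genes,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Serialize all pipeline inputs (and the truth sidecar) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": out / "variants.tsv",
        "gff3": out / "genes.gff3",
        "reference": out / "reference.fa",
        "predictions": out / "predictions.tsv",
        "go": out / "go.gmt",
        "pathways": out / "pathways.gmt",
        "network": out / "network.sif",
        "domains": out / "domains.tsv",
        "cancer_genes": out / "cancer_genes.txt",
        "truth": out / "truth.json",
    }
    ds.variants.to_csv(paths["variants"], sep="\t", index=False)
    iofmt.write_gff3(paths["gff3"], ds.genome.models(), ds.genome.gene_chrom())
    iofmt.write_fasta(paths["reference"], ds.genome.reference)
    ds.predictions.to_csv(paths["predictions"], sep="\t", index=False)
    iofmt.write_gmt(paths["go"], ds.go)
    iofmt.write_gmt(paths["pathways"], ds.pathways)
    iofmt.write_sif(paths["network"], ds.network)
    ds.domains.to_csv(paths["domains"], sep="\t", index=False)
    paths["cancer_genes"].write_text("\n".join(ds.cancer_genes) + "\n")
    paths["truth"].write_text(ds.truth.to_json())
    return paths
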