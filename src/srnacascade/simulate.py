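"""Synthetic-data generation: reference libraries, two-condition raw read
libraries with 3' adapters, and degradome tags with known ground truth.

The generator emulates the statistical structure of a two-library barley
sRNA-seq comparison (transgenic TaDREB3 vs non-transgenic control): a
chloroplast-heavy read population, a single dominant chloroplast tRNA 5'
fragment (the tRNA-His(GTG) phenomenon: ~29% of control reads, ~42% of
transgenic reads), two dominant miRNAs with opposite regulation, designed
per-feature fold changes, adapter-only and untrimmed read classes, and a small
artifact fraction. Counts are Poisson per feature; reads are 36 bases =
insert + 3' adapter prefix (+ random fill for short inserts). Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequtils import random_dna, revcomp

ADAPTER3 = "TCGTATGCCGTCTTCTGCTTGT"  # 3' sequencing adapter, DNA alphabet
ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"
READ_LENGTH = 36
MIN_FEATURE_LENGTH = 17


@dataclass
class BundleConfig:
    n_mirna: int = 20
    mirna_length_range: tuple = (20, 24)
    n_homolog: int = 10
    n_trna: int = 10
    n_repeat: int = 5
    n_gene: int = 30
    chloroplast_length: int = 20_000
    n_novel: int = 20
    n_related_novel: int = 2  # novel loci only on related-species contigs
    n_target_transcripts: int = 20
    precursor_flank: int = 12
    hairpin_arm_extra: int = 8

    def validate(self):
        if self.mirna_length_range[0] < MIN_FEATURE_LENGTH:
            raise ValueError(
                f"feature lengths below the read minimum ({MIN_FEATURE_LENGTH} nt) "
                "are not sequenceable")


@dataclass
class ReferenceBundle:
    chloroplast_genome: str
    trna_his: tuple  # (sequence, 1-based start in chloroplast genome)
    mirna_set: dict  # name -> {"mature", "precursor"}
    homolog_mirna_set: dict  # name -> mature
    ncrna_set: dict  # name -> {"family", "sequence"}
    repeat_set: dict  # name -> {"class", "sequence"}
    gene_set: dict  # name -> sequence
    transgene: tuple  # (name, sequence)
    downstream_genes: dict  # name -> sequence
    novel_mirnas: dict  # name -> mature (planted, ground truth)
    est_contigs: dict  # primary-species contigs holding novel hairpins
    related_contigs: dict  # related-species contigs
    novel_loci: dict  # novel name -> (contig, 1-based start)
    mirna_targets: dict  # novel name -> (transcript, 1-based site of rc block)
    target_transcripts: dict  # transcript name -> sequence

    def to_fasta_dir(self, outdir):
        from .io_utils import ensure_dir, write_fasta

        d = ensure_dir(outdir)
        write_fasta({"chloroplast": self.chloroplast_genome}, d / "chloroplast.fa")
        write_fasta({n: v["mature"] for n, v in self.mirna_set.items()},
                    d / "mirna_mature.fa")
        write_fasta({n: v["precursor"] for n, v in self.mirna_set.items()},
                    d / "mirna_precursor.fa")
        write_fasta(self.homolog_mirna_set, d / "mirna_homolog.fa")
        write_fasta({n: v["sequence"] for n, v in self.ncrna_set.items()},
                    d / "ncrna.fa")
        write_fasta({n: v["sequence"] for n, v in self.repeat_set.items()},
                    d / "repeats.fa")
        write_fasta(self.gene_set, d / "genes.fa")
        write_fasta({self.transgene[0]: self.transgene[1], **self.downstream_genes},
                    d / "transgene_set.fa")
        write_fasta(self.est_contigs, d / "est_contigs.fa")
        write_fasta(self.related_contigs, d / "related_contigs.fa")
        write_fasta(self.target_transcripts, d / "target_transcripts.fa")


def _plant_hairpin(rng, mature: str, arm_extra: int, loop_len: int = 10,
                   flank: int = 12):
    """Precursor with the mature on the 5' arm of a perfect stem."""
    arm = mature + random_dna(rng, arm_extra)
    return (random_dna(rng, flank) + arm + random_dna(rng, loop_len)
            + revcomp(arm) + random_dna(rng, flank))


def generate_reference_bundle(config: BundleConfig | None = None,
                              seed: int = 1) -> ReferenceBundle:
    """Deterministic toy reference libraries with unambiguous ground truth.

    The chloroplast contig carries an embedded tRNA gene whose 5' 19-20 nt
    fragment plays the dominant-tsRNA role. Novel miRNA hairpins are planted
    in EST-like contigs outside every cascade library, and each novel miRNA
    gets a perfectly complementary target site in a separate transcript set
    used by the degradome module.
    """
    config = config or BundleConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    trna_his_seq = random_dna(rng, 74)
    cp = random_dna(rng, config.chloroplast_length)
    trna_start = 2001
    cp = cp[:trna_start - 1] + trna_his_seq + cp[trna_start - 1 + 74:]

    lo, hi = config.mirna_length_range
    mirna_set = {}
    for i in range(config.n_mirna):
        mature = random_dna(rng, int(rng.integers(lo, hi + 1)))
        mirna_set[f"mir{i + 1:03d}"] = {
            "mature": mature,
            "precursor": _plant_hairpin(rng, mature, config.hairpin_arm_extra,
                                        flank=config.precursor_flank),
        }
    homolog = {f"hom-mir{i + 1:03d}": random_dna(rng, int(rng.integers(lo, hi + 1)))
               for i in range(config.n_homolog)}

    ncrna = {}
    for i in range(config.n_trna):
        ncrna[f"tRNA{i + 1:02d}"] = {"family": "tRNA", "sequence": random_dna(rng, 74)}
    for name, fam, ln in (("rRNA5S", "rRNA", 120), ("rRNA25S_frag", "rRNA", 150),
                          ("snoR01", "snoRNA", 100), ("snoR02", "snoRNA", 90),
                          ("U6", "U6", 106), ("U2", "snRNA", 190)):
        ncrna[name] = {"family": fam, "sequence": random_dna(rng, ln)}

    te_classes = ["retrotransposon", "DNA transposon", "unclassified"]
    repeats = {f"TE{i + 1:02d}": {"class": te_classes[i % 3],
                                  "sequence": random_dna(rng, 400)}
               for i in range(config.n_repeat)}

    genes = {f"gene{i + 1:03d}": random_dna(rng, int(rng.integers(300, 601)))
             for i in range(config.n_gene)}
    transgene = ("TaDREB3_transgene", random_dna(rng, 700))
    downstream = {name: random_dna(rng, 400)
                  for name in ("HvCBF15", "HvCBF16", "HvCBF10B", "HvCBF23",
                               "HvCor14B", "HvDHN5", "HvDHN8", "HvDHN9",
                               "HvDHN10")}

    novel, est, related, novel_loci = {}, {}, {}, {}
    for i in range(config.n_novel):
        name = f"novelX{i + 1}"
        mature = random_dna(rng, int(rng.integers(21, 25)))
        novel[name] = mature
        hairpin = _plant_hairpin(rng, mature, config.hairpin_arm_extra,
                                 loop_len=10, flank=0)
        left = random_dna(rng, 80)
        contig = left + hairpin + random_dna(rng, 80)
        start = len(left) + 1  # mature begins the 5' arm (flank=0)
        if i >= config.n_novel - config.n_related_novel:
            cname = f"relatedEST{i + 1:02d}"
            related[cname] = contig
        else:
            cname = f"barleyEST{i + 1:02d}"
            est[cname] = contig
        novel_loci[name] = (cname, start)

    transcripts = {}
    mirna_targets = {}
    names = list(novel)
    for i in range(config.n_target_transcripts):
        tname = f"TC{200000 + i}"
        seq = random_dna(rng, 300)
        if i < len(names):
            m = novel[names[i]]
            site = 150
            seq = seq[:site - 1] + revcomp(m) + seq[site - 1 + len(m):]
            mirna_targets[names[i]] = (tname, site)
        transcripts[tname] = seq

    bundle = ReferenceBundle(cp, (trna_his_seq, trna_start), mirna_set, homolog,
                             ncrna, repeats, genes, transgene, downstream,
                             novel, est, related, novel_loci, mirna_targets,
                             transcripts)
    _check_cross_library(bundle)
    return bundle


def _check_cross_library(bundle: ReferenceBundle):
    """Ground-truth unambiguity: no mature (known or novel) may occur in any
    unrelated library sequence at read length."""
    others = ([bundle.chloroplast_genome]
              + [v["sequence"] for v in bundle.ncrna_set.values()]
              + [v["sequence"] for v in bundle.repeat_set.values()]
              + list(bundle.gene_set.values())
              + [bundle.transgene[1]] + list(bundle.downstream_genes.values()))
    matures = ([v["mature"] for v in bundle.mirna_set.values()]
               + list(bundle.novel_mirnas.values()))
    for m in matures:
        for o in others:
            if m in o or revcomp(m) in o:
                raise RuntimeError(
                    "reference bundle ambiguous: a mature miRNA occurs in "
                    "another library; re-generate with a different seed")


@dataclass
class GroupProfile:
    """Expected composition of one sequencing library."""

    group_label: str
    feature_abundances: dict  # feature name -> expected read count
    total_reads: int  # expectation used to scale abundances
    seed: int
    adapter3: str = ADAPTER3
    adapter5: str = ADAPTER5
    read_length: int = READ_LENGTH
    insert_length_range: tuple = (17, 30)
    adapter_only_rate: float = 0.03
    n_rate: float = 0.004
    homopolymer_rate: float = 0.002
    fold_changes: dict = field(default_factory=dict)  # designed log2, filled later

    def validate(self):
        if any(v < 0 for v in self.feature_abundances.values()):
            raise ValueError("expected counts must be nonnegative")


@dataclass
class FeatureCatalog:
    """Shared emission features: name -> (insert sequence, truth label)."""

    inserts: dict  # name -> insert sequence
    truth: dict  # name -> cascade truth label

    def truth_of(self, sequence: str) -> str | None:
        for name, ins in self.inserts.items():
            if ins == sequence:
                return self.truth[name]
        return None


# fraction-of-total composition for the two study conditions, derived from the
# observed class shares of the real libraries (adapter-only ~3%, untrimmed
# 4-6%, dominant tRNA 5' fragment 28.9% / 42.2%, chloroplast-heavy totals,
# dominant miR156/miR168 analogues ~2% / ~6% with opposite regulation)
_CONTROL_SHARES = {"adapter_only": 0.030, "untrimmed": 0.040,
                   "trna_his": 0.289, "mir_dom_up": 0.0198,
                   "mir_dom_down": 0.0592}
_TRANSGENIC_SHARES = {"adapter_only": 0.036, "untrimmed": 0.059,
                      "trna_his": 0.422, "mir_dom_up": 0.0420,
                      "mir_dom_down": 0.0254}


def _mutate(rng, seq: str, n_subs: int) -> str:
    out = list(seq)
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def build_feature_catalog(bundle: ReferenceBundle, seed: int = 7):
    """Emission features with truth labels, plus per-group fraction tables.

    Returns (catalog, control_fracs, transgenic_fracs) where the fraction
    dicts map feature name -> expected fraction of total reads.
    """
    rng = np.random.default_rng(seed)
    inserts, truth = {}, {}
    fa, fb = {}, {}  # control / transgenic fraction of total reads

    def add(name, insert, label, frac_a, frac_b):
        inserts[name] = insert
        truth[name] = label
        fa[name] = frac_a
        fb[name] = frac_b

    # dominant chloroplast tRNA 5' fragment, 19/20 nt variants
    t_his = bundle.trna_his[0]
    a, b = _CONTROL_SHARES["trna_his"], _TRANSGENIC_SHARES["trna_his"]
    add("trna_his_5p_19", t_his[:19], "chloroplast", 0.35 * a, 0.35 * b)
    add("trna_his_5p_20", t_his[:20], "chloroplast", 0.65 * a, 0.65 * b)

    # untrimmed class: inserts of 27-30 nt leave < 10 adapter bases in the read
    cp = bundle.chloroplast_genome
    for i, ln in enumerate((27, 28, 29, 30)):
        s = 5000 + 200 * i
        add(f"untrimmed_{ln}", cp[s:s + ln], "untrimmed",
            _CONTROL_SHARES["untrimmed"] / 4, _TRANSGENIC_SHARES["untrimmed"] / 4)

    # short inserts (secondary trimming pass; below the 17-nt cascade gate);
    # kept >= 13 nt so chance hits on the chloroplast contig are negligible
    for i, ln in enumerate((13, 14, 15, 15, 16, 16)):
        add(f"short_{i}_{ln}", random_dna(rng, ln), "length_filtered",
            0.004 / 6, 0.003 / 6)

    # known miRNAs: two dominant analogues plus a spread of designed folds
    mir_names = sorted(bundle.mirna_set)
    dom_up, dom_down = mir_names[0], mir_names[1]
    add(f"mature_{dom_up}", bundle.mirna_set[dom_up]["mature"], "mirna_mature",
        _CONTROL_SHARES["mir_dom_up"], _TRANSGENIC_SHARES["mir_dom_up"])
    add(f"mature_{dom_down}", bundle.mirna_set[dom_down]["mature"], "mirna_mature",
        _CONTROL_SHARES["mir_dom_down"], _TRANSGENIC_SHARES["mir_dom_down"])
    # 7 down-regulated (|log2|>=1), 1 up-regulated, rest roughly flat
    deltas = ([-1.3, -1.6, -1.9, -2.2, -1.25, -1.45, -2.4] + [1.8]
              + [0.0, 0.2, -0.3, 0.4, -0.5, 0.1, -0.2, 0.3, -0.8, 0.6])
    for name, delta in zip(mir_names[2:], deltas):
        base = float(rng.uniform(2e-5, 8e-4))
        add(f"mature_{name}", bundle.mirna_set[name]["mature"], "mirna_mature",
            base, base * 2.0 ** delta / 1.38)
    # group-specific miRNAs: present in exactly one library
    spec_a, spec_b = mir_names[-2], mir_names[-1]
    fa[f"mature_{spec_a}"], fb[f"mature_{spec_a}"] = 6e-5, 0.0
    fa[f"mature_{spec_b}"], fb[f"mature_{spec_b}"] = 0.0, 6e-5

    # theoretical star reads for the two dominant miRNAs (computed exactly as
    # the pipeline computes them: fold the precursor, infer the 2-nt overhang)
    from .cascade import infer_star_sequence
    from .novel import fold_hairpin

    for name in (dom_up, dom_down):
        prec = bundle.mirna_set[name]["precursor"]
        star = infer_star_sequence(prec, bundle.mirna_set[name]["mature"],
                                   fold_hairpin(prec).pairs)
        add(f"star_{name}", star, "mirna_mature", 4e-4, 3e-4)

    # isomiRs of the dominant miRNA: 3' +1, 5' -1, one internal substitution
    prec = bundle.mirna_set[dom_up]["precursor"]
    mature = bundle.mirna_set[dom_up]["mature"]
    mstart = prec.find(mature)
    add(f"isomir_{dom_up}_3p+1", prec[mstart:mstart + len(mature) + 1],
        "mirna_isomir", 3e-4, 4e-4)
    add(f"isomir_{dom_up}_5p-1", mature[1:], "mirna_isomir", 2e-4, 1.5e-4)
    sub = _mutate(rng, mature, 1)
    add(f"isomir_{dom_up}_sub1", sub, "mirna_isomir", 1e-4, 1e-4)

    # homolog miRNAs (exact equality stage)
    for i, (name, m) in enumerate(sorted(bundle.homolog_mirna_set.items())[:6]):
        base = float(rng.uniform(2e-5, 2e-4))
        add(f"homolog_{name}", m, "mirna_homolog", base,
            base * 2.0 ** float(rng.uniform(-1.2, 1.2)) / 1.38)

    # ncRNA fragments; Rfam-style matching tolerates 2 substitutions, and the
    # U6 fragment is expression-flat by design (loading control)
    nc_items = sorted(bundle.ncrna_set.items())
    for i, (name, v) in enumerate(nc_items[:10]):
        frag_len = int(rng.integers(20, 25))
        s = int(rng.integers(0, len(v["sequence"]) - frag_len + 1))
        frag = v["sequence"][s:s + frag_len]
        if i == 1:
            frag = _mutate(rng, frag, 1)
        elif i == 2:
            frag = _mutate(rng, frag, 2)
        base = float(rng.uniform(5e-4, 3e-3))
        add(f"ncrna_{name}", frag, "ncrna", base,
            base * 2.0 ** float(rng.uniform(-1.5, 1.0)) / 1.38)
    u6 = bundle.ncrna_set["U6"]["sequence"][10:32]
    add("ncrna_U6", u6, "ncrna", 2e-3, 2e-3 / 1.38)

    # repeat-derived sRNAs (>= 20 nt to clear the repeat-stage length rule)
    for i, (name, v) in enumerate(sorted(bundle.repeat_set.items())):
        frag_len = int(rng.integers(20, 25))
        s = int(rng.integers(0, len(v["sequence"]) - frag_len + 1))
        delta = -1.5 if i < 2 else float(rng.uniform(-0.8, 0.3))
        base = float(rng.uniform(1e-4, 6e-4))
        add(f"repeat_{name}", v["sequence"][s:s + frag_len], "repeat",
            base, base * 2.0 ** delta / 1.38)

    # natsiRNAs: antisense gene fragments, incl. two perfect-inclusion chains
    gene_items = sorted(bundle.gene_set.items())
    for gi, (gname, gseq) in enumerate(gene_items[:5]):
        frag = revcomp(gseq[50:74])
        base = float(rng.uniform(1e-4, 5e-4))
        add(f"nat_{gname}", frag, "gene_antisense", base,
            base * 2.0 ** float(rng.uniform(-1.0, 1.5)) / 1.38)
    for gname, gseq in gene_items[5:7]:
        frag = revcomp(gseq[100:124])
        base = float(rng.uniform(1e-4, 4e-4))
        for sub_len in (24, 21, 18):
            add(f"nat_{gname}_{sub_len}", frag[:sub_len], "gene_antisense",
                base, base * 0.9 / 1.38)

    # transgene-derived sRNAs: transgenic library only, sense hits clustered at
    # the 3' region plus antisense reads overlapping them
    tg = bundle.transgene[1]
    for i, s in enumerate((600, 620, 640, 655)):
        add(f"transgene_sense_{i}", tg[s:s + 21], "transgene", 0.0, 4e-4)
    for i, s in enumerate((605, 645)):
        add(f"transgene_anti_{i}", revcomp(tg[s:s + 22]), "transgene", 0.0, 1.5e-4)
    # downstream-gene sRNAs (both groups, control-heavier)
    for name, seq in sorted(bundle.downstream_genes.items())[:5]:
        base = float(rng.uniform(1e-4, 3e-4))
        add(f"downstream_{name}", seq[200:222], "transgene", base, base * 0.5)
        add(f"downstream_{name}_anti", revcomp(seq[240:262]), "transgene",
            base * 0.6, base * 0.25)

    # novel miRNAs: fractions shaped like the published candidate counts
    # (7 down-regulated, 1 up-regulated, most low-abundance)
    novel_deltas = [0.15, -0.09, -1.85, 1.79, -0.9, -0.02, -1.25, 0.2, -1.89,
                    -1.58, -0.63, -0.6, -0.15, -0.97, -0.7, -1.66, -0.75,
                    -2.41, 0.15, -1.72]
    novel_bases = [2.5e-4, 8e-4, 6e-5, 4e-5, 2e-4, 3e-3, 2.5e-4, 5e-5, 1.5e-4,
                   8e-5, 1e-3, 1e-4, 6e-5, 1.2e-4, 5e-5, 6e-4, 7e-5, 6e-5,
                   5e-5, 1.3e-4]
    for (name, m), base, delta in zip(sorted(bundle.novel_mirnas.items()),
                                      novel_bases, novel_deltas):
        add(f"novel_{name}", m, "unassigned", base, base * 2.0 ** delta / 1.38)

    # pin the expected non-chloroplast total ratio at the study's observed
    # normalization factor (~1.3832): uniform rescale of the transgenic
    # non-chloroplast mass (a uniform rescale shifts all designed log2 values
    # equally and is exactly undone by the pipeline's normalization)
    noncp = [k for k, lab in truth.items()
             if lab not in ("chloroplast", "untrimmed", "length_filtered")]
    target = sum(fa[k] for k in noncp) / 1.3831699166
    current = sum(fb[k] for k in noncp)
    for k in noncp:
        fb[k] *= target / current

    # chloroplast background fills the remaining mass so each group's
    # designed fractions sum to (1 - artifact rates)
    n_cp_windows = 40
    cp_share_a = 1.0 - sum(fa.values()) - 0.030 - 0.004 - 0.002
    cp_share_b = 1.0 - sum(fb.values()) - 0.036 - 0.004 - 0.002
    assert cp_share_a > 0 and cp_share_b > 0
    weights = rng.dirichlet(np.full(n_cp_windows, 2.0))
    for i in range(n_cp_windows):
        ln = int(rng.integers(17, 27))
        s = int(rng.integers(0, len(cp) - ln))
        if bundle.trna_his[1] - ln < s < bundle.trna_his[1] + 74:
            s = (s + 200) % (len(cp) - ln)
        frag = cp[s:s + ln]
        if i % 5 == 4:
            frag = revcomp(frag)
        skew = float(rng.uniform(0.6, 1.6))
        add(f"cp_window_{i:02d}", frag, "chloroplast",
            cp_share_a * weights[i], cp_share_b * weights[i] * skew)
    # renormalize the transgenic chloroplast mass after the skew
    tot_b = sum(v for k, v in fb.items() if k.startswith("cp_window"))
    for k in list(fb):
        if k.startswith("cp_window"):
            fb[k] *= cp_share_b / tot_b

    catalog = FeatureCatalog(inserts, truth)
    if len(set(inserts.values())) != len(inserts):
        raise RuntimeError("duplicate insert sequences in feature catalog")
    return catalog, fa, fb


def default_profiles(bundle: ReferenceBundle, total_reads: int = 100_000,
                     seed: int = 7):
    """The two study-condition profiles plus the shared feature catalog."""
    catalog, fa, fb = build_feature_catalog(bundle, seed=seed)
    control = GroupProfile(
        "control", {k: v * total_reads for k, v in fa.items()}, total_reads,
        seed=seed + 1, adapter_only_rate=_CONTROL_SHARES["adapter_only"])
    transgenic = GroupProfile(
        "transgenic", {k: v * total_reads for k, v in fb.items()}, total_reads,
        seed=seed + 2, adapter_only_rate=_TRANSGENIC_SHARES["adapter_only"])
    control.validate()
    transgenic.validate()
    return catalog, control, transgenic


def designed_table(catalog: FeatureCatalog, control: GroupProfile,
                   transgenic: GroupProfile) -> pd.DataFrame:
    """Ground-truth per-feature expectations and designed log2 ratios.

    The designed log2 of a shared non-chloroplast feature is
    log2(E_B * F / E_A) with F the ratio of the two groups' expected
    non-chloroplast insert totals — exactly the quantity the pipeline
    estimates after its own normalization.
    """
    non_cp = [k for k, lab in catalog.truth.items()
              if lab not in ("chloroplast", "untrimmed", "length_filtered")]
    tot_a = sum(control.feature_abundances.get(k, 0.0) for k in non_cp)
    tot_b = sum(transgenic.feature_abundances.get(k, 0.0) for k in non_cp)
    factor = tot_a / tot_b
    rows = []
    for name in catalog.inserts:
        ea = control.feature_abundances.get(name, 0.0)
        eb = transgenic.feature_abundances.get(name, 0.0)
        designed = (np.log2(eb * factor / ea)
                    if (ea > 0 and eb > 0 and name in non_cp) else np.nan)
        rows.append({"feature": name, "insert": catalog.inserts[name],
                     "truth": catalog.truth[name], "expected_control": ea,
                     "expected_transgenic": eb, "designed_log2": designed})
    return pd.DataFrame(rows)


def generate_read_library(bundle: ReferenceBundle, profile: GroupProfile,
                          catalog: FeatureCatalog) -> list[str]:
    """Raw 36-base reads for one library: per-feature Poisson counts, each read
    = insert + 3' adapter prefix, random-filled/truncated to 36 bases, plus
    adapter-only, N-containing and homopolymer artifact reads. Byte-identical
    output under a fixed profile seed."""
    profile.validate()
    if profile.total_reads == 0:
        raise ValueError("total_reads must be positive")
    rng = np.random.default_rng(profile.seed)
    reads = []

    def finish(insert):
        read = insert + profile.adapter3
        if len(read) < profile.read_length:
            read += random_dna(rng, profile.read_length - len(read))
        return read[:profile.read_length]

    for name in sorted(profile.feature_abundances):
        expected = profile.feature_abundances[name]
        if expected <= 0:
            continue
        n = int(rng.poisson(expected))
        insert = catalog.inserts[name]
        reads.extend(finish(insert) for _ in range(n))

    n_adapter_only = int(rng.poisson(profile.adapter_only_rate * profile.total_reads))
    reads.extend(finish("") for _ in range(n_adapter_only))
    n_n = int(rng.poisson(profile.n_rate * profile.total_reads))
    for _ in range(n_n):
        read = list(finish(random_dna(rng, 20)))
        read[int(rng.integers(0, len(read)))] = "N"
        reads.append("".join(read))
    n_homo = int(rng.poisson(profile.homopolymer_rate * profile.total_reads))
    for _ in range(n_homo):
        reads.append(str(rng.choice(list("ACGT"))) * profile.read_length)

    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def generate_degradome_tags(bundle: ReferenceBundle, mirna_targets: dict,
                            seed: int = 1, alternative_fraction: float = 0.0,
                            copies: int = 3) -> list[tuple[str, str]]:
    """Degradome tags for declared miRNA target sites.

    A site declares a transcript position where the reverse complement of the
    mature is embedded; the canonical tag starts at the base pairing miRNA
    position 10 and runs 20-21 nt 3'-ward, so its 5' portion is the reverse
    complement of miRNA positions 10..1. A fraction of miRNAs instead use an
    alternative position in 11-15. Sites too close to the transcript 3' end
    are skipped with a warning. Returns [(name, tag sequence), ...].
    """
    rng = np.random.default_rng(seed)
    tags = []
    for mirna_name in sorted(mirna_targets):
        tname, site = mirna_targets[mirna_name]
        transcript = bundle.target_transcripts[tname]
        mature = (bundle.novel_mirnas.get(mirna_name)
                  or bundle.mirna_set.get(mirna_name, {}).get("mature"))
        if mature is None:
            raise KeyError(f"unknown miRNA {mirna_name}")
        L = len(mature)
        p = 10
        if alternative_fraction > 0 and rng.random() < alternative_fraction:
            p = int(rng.integers(11, 16))
        tag_len = int(rng.choice((20, 21)))
        start = site + L - p  # 1-based tag start on the transcript
        if start - 1 + tag_len > len(transcript):
            warnings.warn(f"site for {mirna_name} too close to the 3' end of "
                          f"{tname}; skipped")
            continue
        tag = transcript[start - 1:start - 1 + tag_len]
        for c in range(copies):
            tags.append((f"{mirna_name}_tag{c + 1}", tag))
    return tags
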