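"""Synthetic diverged genome pairs and group-structured methylomes.

The generator emulates the divergence structure measured between two cattle
assemblies (Brahman x Angus style): ~0.4% substitutions enriched ~13-fold at
CpG bases with ~81% of CpG-site changes being C>T / G>A (spontaneous
deamination of methylated cytosine), insertion/deletion structural variants
whose inserted material carries ~1.18x the background CpG density, plus
beta-binomial WGBS-style methylation calls for four reciprocal-cross groups
(BTBT, BTBI, BIBT, BIBI) at ~30x site coverage with planted DMRs and
breed-specific-CpG methylation offsets.

Every operation is a pure function of its inputs and an integer seed; the
same config and seed reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coords import CoordinateMap

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

GROUPS = ("BTBT", "BTBI", "BIBT", "BIBI")


@dataclass
class SynthConfig:
    """Parameters of one diverged genome pair.

    snp_rate is the per-base substitution probability at non-CpG bases;
    CpG bases mutate at snp_rate * cpg_snp_fold, and those substitutions are
    C>T (or G>A on the G) with probability cpg_transition_fraction.
    Inserted SV sequence is drawn with an elevated G+C so its expected CpG
    dinucleotide density is sv_cpg_density_fold times the background.
    """

    n_chrom: int = 2
    chrom_len: int = 500_000
    gc_fraction: float = 0.42
    snp_rate: float = 0.004
    cpg_snp_fold: float = 13.0
    cpg_transition_fraction: float = 0.81
    sv_count: int = 20
    sv_len_range: tuple[int, int] = (50, 2_000)
    sv_cpg_density_fold: float = 1.18
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "snp_rate", "cpg_transition_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.chrom_len < 2_000:
            raise ValueError("chrom_len must be >= 2,000 (room for 500-bp flank exclusion)")
        if self.sv_len_range[0] < 50:
            raise ValueError("SVs are indels >= 50 bp; sv_len_range min must be >= 50")
        if self.snp_rate * self.cpg_snp_fold > 1.0:
            raise ValueError("snp_rate * cpg_snp_fold exceeds 1")


@dataclass
class VariantTruth:
    """Planted variants, in source-genome coordinates.

    snps: (chrom, pos0, ref_base, alt_base)
    svs:  (chrom, start0, end0, type 'ins'|'del', length, sequence) where for
          insertions end0 == start0 and sequence is the inserted material,
          and for deletions end0 - start0 == length and sequence is the
          deleted source material.
    """

    snps: list[tuple[str, int, str, str]] = field(default_factory=list)
    svs: list[tuple[str, int, int, str, int, str]] = field(default_factory=list)


@dataclass
class MethylomeTruth:
    """Ground-truth methylation model.

    baseline_p: None draws a bimodal WGBS-like baseline per CpG (mixture of
    high- and low-methylation Beta components, global mean ~0.55); a float
    applies one constant baseline everywhere.
    planted_dmrs: (chrom, start0, end0, groups, delta_p) in source (ancestral)
    coordinates; ``groups`` is an iterable of group labels whose samples get
    baseline + delta_p inside the interval.
    breed_specific_offset: delta added at breed-specific CpGs of each
    reference, keyed by reference label (negative = hypomethylated, the
    direction seen in real breed-specific sites).
    dispersion: beta-binomial overdispersion rho in [0,1); 0 is binomial.
    mean_coverage: mean destranded site depth (split across the two strands).
    """

    baseline_p: float | None = None
    planted_dmrs: list[tuple[str, int, int, tuple[str, ...], float]] = field(default_factory=list)
    breed_specific_offset: dict[str, float] = field(default_factory=dict)
    dispersion: float = 0.02
    mean_coverage: float = 30.0


def default_sample_sheet(n_per_group: int = 6) -> pd.DataFrame:
    """Four reciprocal-cross groups, sexes alternating within each group."""
    rows = []
    for g in GROUPS:
        for i in range(n_per_group):
            rows.append((f"{g}_{i + 1}", g, "M" if i % 2 == 0 else "F"))
    return pd.DataFrame(rows, columns=["sample_id", "group", "sex"])


# ---------------------------------------------------------------- genome


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=length, p=p)]


def generate_genome(config: SynthConfig) -> dict[str, str]:
    """i.i.d. random chromosomes chr1..chrN at the configured G+C."""
    rng = np.random.default_rng(config.seed)
    return {
        f"chr{i + 1}": _random_seq(rng, config.chrom_len, config.gc_fraction).tobytes().decode()
        for i in range(config.n_chrom)
    }


def expected_cpg_count(length: int, gc: float) -> float:
    """Closed-form expected CG dinucleotide count of the i.i.d. emission model."""
    return (length - 1) * (gc / 2) ** 2


# ---------------------------------------------------------------- divergence


def _cpg_base_mask(arr: np.ndarray) -> np.ndarray:
    """Boolean mask over bases that are part of a forward-strand CG."""
    is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    mask = np.zeros(arr.size, dtype=bool)
    mask[:-1] |= is_cg
    mask[1:] |= is_cg
    return mask


def diverge_genome(
    genome: dict[str, str], config: SynthConfig
) -> tuple[dict[str, str], VariantTruth, CoordinateMap]:
    """Derive a second assembly by planting SNPs and SVs.

    SNP placement avoids SV footprints (and SV placement avoids nothing but
    other SVs and chromosome ends), so the truth is unambiguous: applying the
    recorded edits to the source reproduces the derived genome byte-for-byte.
    """
    if not genome:
        raise ValueError("empty genome")
    rng = np.random.default_rng(config.seed + 1)
    derived: dict[str, str] = {}
    truth = VariantTruth()
    blocks = []

    total_len = sum(len(s) for s in genome.values())
    gc_ins = min(1.0, config.gc_fraction * np.sqrt(config.sv_cpg_density_fold))

    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        L = arr.size

        # --- SVs: non-overlapping, away from chromosome ends
        n_sv = int(round(config.sv_count * L / total_len))
        svs = []
        occupied: list[tuple[int, int]] = []
        cg_density = (config.gc_fraction / 2) ** 2
        for _ in range(n_sv):
            placed = False
            for _try in range(1000):
                length = int(rng.integers(config.sv_len_range[0], config.sv_len_range[1] + 1))
                typ = "del" if rng.random() < 0.5 else "ins"
                span = length if typ == "del" else 0
                if typ == "ins":
                    start = int(rng.integers(600, L - 600 - span))
                    if any(not (start + span + 100 <= s or start - 100 >= e) for s, e in occupied):
                        continue
                    ins_seq = _random_seq(rng, length, gc_ins).tobytes().decode()
                    svs.append((chrom, start, start, "ins", length, ins_seq))
                else:
                    # deleted material must also carry ~fold x background CpG
                    # density (real SVs are CpG-enriched whichever genome
                    # carries them): among candidate loci pick the one whose
                    # CpG count is closest to fold x expectation
                    target = config.sv_cpg_density_fold * (length - 1) * cg_density
                    best = None
                    for _c in range(40):
                        cand = int(rng.integers(600, L - 600 - span))
                        if any(not (cand + span + 100 <= s or cand - 100 >= e) for s, e in occupied):
                            continue
                        seg = arr[cand : cand + length]
                        n_cg = int(np.sum((seg[:-1] == ord("C")) & (seg[1:] == ord("G"))))
                        err = abs(n_cg - target)
                        if best is None or err < best[0]:
                            best = (err, cand, n_cg)
                    if best is None:
                        continue
                    start = best[1]
                    svs.append((chrom, start, start + length, "del", length, seq[start : start + length]))
                occupied.append((start, start + span))
                placed = True
                break
            if not placed:
                raise RuntimeError(f"could not place SV on {chrom} without overlap")
        svs.sort(key=lambda r: r[1])

        sv_footprint = np.zeros(L, dtype=bool)
        for _, s, e, typ, _, _ in svs:
            sv_footprint[s:e] = True
            if typ == "ins":  # keep the insertion breakpoint clean for the map
                sv_footprint[max(0, s - 1) : s + 1] = True

        # --- SNPs
        cpg = _cpg_base_mask(arr)
        rate = np.where(cpg, config.snp_rate * config.cpg_snp_fold, config.snp_rate)
        hit = (rng.random(L) < rate) & ~sv_footprint
        pos = np.flatnonzero(hit)
        for p in pos:
            ref = chr(arr[p])
            if cpg[p] and ref in "CG":
                deam = "T" if ref == "C" else "A"
                if rng.random() < config.cpg_transition_fraction:
                    alt = deam
                else:  # the non-deamination remainder excludes the deamination change
                    alt = rng.choice([b for b in "ACGT" if b not in (ref, deam)])
            else:
                alt = rng.choice([b for b in "ACGT" if b != ref])
            truth.snps.append((chrom, int(p), ref, str(alt)))
            arr[p] = ord(alt)

        # --- apply SVs and build the map
        pieces = []
        src_cursor = 0
        dst_cursor = 0
        for _, s, e, typ, length, sv_seq in svs:
            if s > src_cursor:
                pieces.append(arr[src_cursor:s].tobytes().decode())
                blocks.append((chrom, src_cursor, s, chrom, dst_cursor, dst_cursor + (s - src_cursor)))
                dst_cursor += s - src_cursor
            if typ == "del":
                src_cursor = e
            else:
                pieces.append(sv_seq)
                dst_cursor += length
                src_cursor = s
            truth.svs.append((chrom, s, e, typ, length, sv_seq))
        if src_cursor < L:
            pieces.append(arr[src_cursor:].tobytes().decode())
            blocks.append((chrom, src_cursor, L, chrom, dst_cursor, dst_cursor + (L - src_cursor)))
        derived[chrom] = "".join(pieces)

    return derived, truth, CoordinateMap(blocks)


def apply_variants(genome: dict[str, str], truth: VariantTruth) -> dict[str, str]:
    """Re-apply recorded edits; used to verify truth coherence."""
    out = {}
    snps_by_chrom: dict[str, list] = {}
    for chrom, p, ref, alt in truth.snps:
        snps_by_chrom.setdefault(chrom, []).append((p, ref, alt))
    svs_by_chrom: dict[str, list] = {}
    for sv in truth.svs:
        svs_by_chrom.setdefault(sv[0], []).append(sv)
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        for p, ref, alt in snps_by_chrom.get(chrom, []):
            if chr(arr[p]) != ref:
                raise ValueError(f"truth ref mismatch at {chrom}:{p}")
            arr[p] = ord(alt)
        pieces = []
        cursor = 0
        for _, s, e, typ, length, sv_seq in sorted(svs_by_chrom.get(chrom, []), key=lambda r: r[1]):
            pieces.append(arr[cursor:s].tobytes().decode())
            if typ == "ins":
                pieces.append(sv_seq)
                cursor = s
            else:
                cursor = e
        pieces.append(arr[cursor:].tobytes().decode())
        out[chrom] = "".join(pieces)
    return out


def classification_truth(genome: dict[str, str], truth: VariantTruth) -> pd.DataFrame:
    """Expected cross-assembly class of every source-genome CpG.

    shared: neither base hit by a SNP and the site is outside SV footprints;
    snp_affected: exactly one of the two bases substituted;
    unresolved: both bases substituted;
    breed_specific: the site lies inside a deleted segment.

    ``ambiguous`` marks sites whose 1,002-bp flank touches an SV footprint
    (within 510 bp of a breakpoint): there the mapped class depends on
    alignment details rather than on the planted truth alone.
    """
    from .cpg_catalog import cpg_positions

    snp_pos: dict[str, set] = {}
    for chrom, p, _, _ in truth.snps:
        snp_pos.setdefault(chrom, set()).add(p)
    rows = []
    for chrom, seq in genome.items():
        hits = snp_pos.get(chrom, set())
        svs = [s for s in truth.svs if s[0] == chrom]
        dels = [(s[1], s[2]) for s in svs if s[3] == "del"]
        amb_iv = [(s[1] - 512, s[2] + 512) for s in svs]
        for pos in cpg_positions(seq):
            pos = int(pos)
            if any(s <= pos < e for s, e in dels):
                cls = "breed_specific"
            else:
                n_hit = (pos in hits) + ((pos + 1) in hits)
                cls = {0: "shared", 1: "snp_affected", 2: "unresolved"}[n_hit]
            amb = any(s <= pos < e for s, e in amb_iv)
            rows.append((chrom, pos, cls, amb))
    return pd.DataFrame(rows, columns=["chrom", "pos0", "true_cls", "ambiguous"])


# ---------------------------------------------------------------- uniform mutator


def mutate_uniform(genome, n_subs: int, seed: int):
    """Exactly n_subs substitutions at distinct uniform positions.

    Mirrors a SNP-Mutator style validation run: accepts one sequence (str)
    or a {chrom: seq} dict; positions are drawn over the concatenated length.
    Returns (mutated genome in the same shape, truth list of
    (chrom, pos0, ref, alt)).
    """
    single = isinstance(genome, str)
    gdict = {"seq": genome} if single else genome
    chroms = list(gdict)
    lengths = np.array([len(gdict[c]) for c in chroms])
    total = int(lengths.sum())
    if n_subs > total:
        raise ValueError(f"n_subs={n_subs} exceeds genome length {total}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_subs, replace=False)
    flat.sort()
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    arrs = {c: np.frombuffer(gdict[c].encode(), dtype=np.uint8).copy() for c in chroms}
    truth = []
    idx = np.searchsorted(bounds, flat, side="right") - 1
    for f, ci in zip(flat, idx):
        chrom = chroms[ci]
        p = int(f - bounds[ci])
        ref = chr(arrs[chrom][p])
        choices = [b for b in "ACGT" if b != ref] or list("ACGT")
        alt = str(rng.choice(choices))
        if ref in "ACGT":
            arrs[chrom][p] = ord(alt)
            truth.append((chrom, p, ref, alt))
        else:  # ambiguity code: substitute with a random base
            arrs[chrom][p] = ord(alt)
            truth.append((chrom, p, ref, alt))
    mutated = {c: arrs[c].tobytes().decode() for c in chroms}
    return (mutated["seq"] if single else mutated), truth


# ---------------------------------------------------------------- methylomes

from .io import MethylationCallSet  # noqa: E402  (avoids a hard cycle at import time)


def _draw_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal WGBS-like baseline: 60% high-methylation, 40% low; mean ~0.56."""
    hi = rng.beta(8, 2, size=n)
    lo = rng.beta(2, 8, size=n)
    return np.where(rng.random(n) < 0.6, hi, lo)


def _beta_binomial(rng, cov: np.ndarray, p: np.ndarray, rho: float) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    if rho <= 0:
        return rng.binomial(cov, p)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    ps = np.where((p > 0) & (p < 1), rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12)), p)
    return rng.binomial(cov, ps)


def simulate_methylomes(
    genomes: dict[str, dict[str, str]],
    coord_map: CoordinateMap,
    meth_truth: MethylomeTruth,
    sample_sheet: pd.DataFrame,
    seed: int,
    ref_labels: tuple[str, str] = ("A", "B"),
) -> dict[tuple[str, str], MethylationCallSet]:
    """Emit stranded call sets for every (sample, reference).

    ``genomes`` maps each of the two reference labels to its sequence dict;
    ``coord_map`` maps reference A coordinates to reference B. Shared CpGs
    (mapped position, CG in both) carry one latent methylation level emitted
    in both coordinate systems; CpGs private to one reference get the
    configured breed-specific offset and appear only there.

    Returns {(sample_id, ref_label): MethylationCallSet}. Coverage per strand
    is Poisson(mean_coverage / 2) floored at 1, so the destranded site depth
    averages mean_coverage; methylated counts are beta-binomial.
    """
    from .cpg_catalog import enumerate_cpgs

    ref_a, ref_b = ref_labels
    rng = np.random.default_rng(seed)
    cat = {lbl: enumerate_cpgs(genomes[lbl]) for lbl in ref_labels}

    # pair A sites with B sites through the map
    a_sites = list(cat[ref_a].itertuples(index=False))
    b_index = {(r.chrom, r.pos0) for r in cat[ref_b].itertuples(index=False)}
    pair_of_a = {}
    matched_b = set()
    for r in a_sites:
        hit = coord_map.map_pos(r.chrom, r.pos0)
        if hit is not None and hit in b_index:
            pair_of_a[(r.chrom, r.pos0)] = hit
            matched_b.add(hit)

    # latent site table: one row per distinct biological CpG
    rows = []  # (a_key or None, b_key or None)
    for r in a_sites:
        k = (r.chrom, r.pos0)
        rows.append((k, pair_of_a.get(k)))
    for r in cat[ref_b].itertuples(index=False):
        k = (r.chrom, r.pos0)
        if k not in matched_b:
            rows.append((None, k))
    n = len(rows)
    if meth_truth.baseline_p is None:
        baseline = _draw_baseline(rng, n)
    else:
        baseline = np.full(n, float(meth_truth.baseline_p))

    off_a = meth_truth.breed_specific_offset.get(ref_a, 0.0)
    off_b = meth_truth.breed_specific_offset.get(ref_b, 0.0)
    base_off = np.zeros(n)
    for i, (ka, kb) in enumerate(rows):
        if ka is not None and kb is None:
            base_off[i] = off_a
        elif ka is None and kb is not None:
            base_off[i] = off_b

    # planted DMR deltas are defined on reference-A coordinates
    dmr_delta_by_group: dict[str, np.ndarray] = {g: np.zeros(n) for g in sample_sheet["group"].unique()}
    a_pos = np.array([(-1 if ka is None else ka[1]) for ka, _ in rows])
    a_chrom = np.array([("" if ka is None else ka[0]) for ka, _ in rows])
    for chrom, s, e, groups, delta in meth_truth.planted_dmrs:
        inside = (a_chrom == chrom) & (a_pos >= s) & (a_pos < e)
        for g in groups:
            if g not in dmr_delta_by_group:
                raise ValueError(f"planted DMR references unknown group {g}")
            dmr_delta_by_group[g][inside] += delta

    lam = meth_truth.mean_coverage / 2.0
    out: dict[tuple[str, str], MethylationCallSet] = {}
    for samp in sample_sheet.itertuples(index=False):
        p_eff = np.clip(baseline + base_off + dmr_delta_by_group[samp.group], 0.0, 1.0)
        for lbl, key_col in ((ref_a, 0), (ref_b, 1)):
            keys = [row[key_col] for row in rows]
            sel = np.array([k is not None for k in keys])
            idx = np.flatnonzero(sel)
            m = idx.size
            cov_f = np.maximum(1, rng.poisson(lam, size=m))
            cov_r = np.maximum(1, rng.poisson(lam, size=m))
            meth_f = _beta_binomial(rng, cov_f, p_eff[idx], meth_truth.dispersion)
            meth_r = _beta_binomial(rng, cov_r, p_eff[idx], meth_truth.dispersion)
            chroms = [keys[i][0] for i in idx]
            poss = np.array([keys[i][1] for i in idx])
            df = pd.DataFrame(
                {
                    "chrom": np.concatenate([chroms, chroms]),
                    "pos0": np.concatenate([poss, poss + 1]),
                    "strand": ["+"] * m + ["-"] * m,
                    "coverage": np.concatenate([cov_f, cov_r]),
                    "n_meth": np.concatenate([meth_f, meth_r]),
                }
            ).sort_values(["chrom", "pos0"], kind="mergesort").reset_index(drop=True)
            out[(samp.sample_id, lbl)] = MethylationCallSet(samp.sample_id, lbl, df, stranded=True)
    return out


def planted_dmr_table(meth_truth: MethylomeTruth) -> pd.DataFrame:
    """Echo the configured planted DMRs as a table (truth export)."""
    return pd.DataFrame(
        [(c, s, e, ",".join(g), d) for c, s, e, g, d in meth_truth.planted_dmrs],
        columns=["chrom", "start0", "end0", "groups", "delta_p"],
    )


# ---------------------------------------------------------------- genes / DEGs


def simulate_genes_and_degs(
    genome: dict[str, str], n_genes: int, n_deg: int, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place non-overlapping gene bodies and mark a DEG subset.

    Returns (genes, degs): genes has chrom/start0/end0/strand/gene_id; degs
    has gene_id/direction/padj with n_deg rows.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    rows = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for i in range(n_genes):
        for _try in range(2000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            glen = int(rng.integers(2_000, 20_001))
            if lengths[chrom] <= glen + 1:
                continue
            start = int(rng.integers(0, lengths[chrom] - glen))
            if any(not (start + glen + 1_000 <= s or start - 1_000 >= e) for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, start + glen))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, start, start + glen, strand, f"G{i + 1:04d}"))
            break
        else:
            raise RuntimeError("could not place gene without overlap")
    genes = pd.DataFrame(rows, columns=["chrom", "start0", "end0", "strand", "gene_id"])
    genes = genes.sort_values(["chrom", "start0"]).reset_index(drop=True)
    deg_ids = rng.choice(genes["gene_id"].to_numpy(), size=n_deg, replace=False)
    degs = pd.DataFrame(
        {
            "gene_id": deg_ids,
            "direction": rng.choice(["up", "down"], size=n_deg),
            "padj": rng.uniform(1e-8, 0.05, size=n_deg),
        }
    )
    return genes, degs
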