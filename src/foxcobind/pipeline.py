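"""End-to-end orchestration: simulate a synthetic study, run every analysis
stage in dependency order, and emit a machine-readable report plus TSV tables.

All randomness flows from one master seed, split into fixed per-stage
substreams, so a rerun with the same inputs and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import annotate_assoc, flanking_pref, motif_analysis, peak_ops
from . import synthetic_data as synth
from . import tag_profile as tp
from .io_formats import (Genome, PeakSet, RunConfig, classify_regulation,
                         read_expression_table, read_fasta, read_gene_models,
                         read_peaks, read_tags, write_expression_table,
                         write_fasta, write_gene_models, write_peaks,
                         write_tags)

CORE_MOTIF = "GTAAACA"
BROAD_MOTIF = "ATGTAAACAAS"


def _stage_seed(master: int, stage: str) -> int:
    """Stable per-stage substream seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# synthetic study bundle
# ---------------------------------------------------------------------------

DEFAULT_CLASS_COUNTS: dict[frozenset[str], int] = {
    frozenset({"K2"}): 30,
    frozenset({"O3"}): 15,
    frozenset({"J3"}): 15,
    frozenset({"K2", "O3"}): 25,
    frozenset({"K2", "J3"}): 15,
    frozenset({"O3", "J3"}): 10,
    frozenset({"K2", "O3", "J3"}): 25,
}

DEFAULT_ASSOC = {
    frozenset({"K2"}): (0.10, 0.60),
    frozenset({"O3"}): (0.60, 0.10),
    frozenset({"J3"}): (0.10, 0.50),
    frozenset({"K2", "O3"}): (0.60, 0.10),
    frozenset({"K2", "J3"}): (0.15, 0.45),
    frozenset({"O3", "J3"}): (0.55, 0.10),
    frozenset({"K2", "O3", "J3"}): (0.70, 0.05),
}


def simulate_study(out_dir: str | Path, seed: int,
                   class_counts: Mapping[frozenset[str], int] | None = None,
                   assoc_probs: Mapping[frozenset[str], tuple[float, float]]
                   | None = None,
                   n_chroms: int = 2, chrom_len: int = 1_200_000,
                   n_signal: int = 20_000, n_background: int = 5_000,
                   n_filler_genes: int = 60,
                   flank_spec: synth.FlankPrefSpec | None = None,
                   config: RunConfig | None = None) -> dict:
    """Generate and write a complete synthetic study bundle.

    Emits genome.fa, {factor}_{callerA,callerB}.narrowPeak, tags_{factor}.bed,
    genes.tsv, expression.tsv and truth.json; returns the input manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()
    class_counts = dict(class_counts or DEFAULT_CLASS_COUNTS)
    assoc_probs = dict(assoc_probs or DEFAULT_ASSOC)
    if flank_spec is None:
        # the planted factor-intrinsic preference: A-rich immediately 5' of
        # the core, mirroring an upstream A/T preference
        flank_spec = (synth.FlankPrefSpec.uniform(5)
                      .with_preference(-2, "A", 0.9)
                      .with_preference(-1, "T", 0.9))

    arch = synth.ArchitectureSpec(class_counts=class_counts)
    genome = synth.simulate_genome(n_chroms, chrom_len,
                                   seed=_stage_seed(seed, "genome"))
    peak_sets, truth = synth.simulate_architecture(
        genome, arch, seed=_stage_seed(seed, "architecture"))
    genome = synth.plant_motifs(genome, truth, CORE_MOTIF, flank_spec, arch,
                                seed=_stage_seed(seed, "motifs"))
    primary, confirm = synth.simulate_confirm_sets(
        peak_sets, genome, seed=_stage_seed(seed, "callers"))

    assoc = synth.AssociationSpec(class_probs=assoc_probs,
                                  n_filler_genes=n_filler_genes)
    genes, expr = synth.simulate_genes_and_expression(
        genome, truth, assoc, config, seed=_stage_seed(seed, "genes"))

    write_fasta(genome, out_dir / "genome.fa")
    # occupancy proportional to the number of co-binding factors, so average
    # tag density rises from factor-specific to triple-shared regions
    class_size = {r.region_id: len(r.cls) for r in truth.regions}
    manifest: dict = {"seed": seed, "factors": [], "genome": "genome.fa"}
    for label in sorted(primary):
        a = f"{label}_callerA.narrowPeak"
        b = f"{label}_callerB.narrowPeak"
        t = f"tags_{label}.bed"
        write_peaks(primary[label], out_dir / a)
        write_peaks(confirm[label], out_dir / b)
        weights = [class_size.get(p.name.rsplit("_", 1)[0], 1)
                   for p in peak_sets[label]]
        track = synth.simulate_tags(
            genome, peak_sets[label], n_signal, n_background,
            placement_sd=50.0, fragment_len=config.fragment_len,
            weights=weights,
            seed=_stage_seed(seed, f"tags:{label}"))
        write_tags(track, out_dir / t)
        manifest["factors"].append(
            {"label": label, "peaks_primary": a, "peaks_confirm": b,
             "tags": t})
    write_gene_models(genes, out_dir / "genes.tsv")
    write_expression_table(expr, out_dir / "expression.tsv")
    truth.to_json(out_dir / "truth.json")
    manifest["genes"] = "genes.tsv"
    manifest["expression"] = "expression.tsv"
    manifest["truth"] = "truth.json"
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def _sample_background_summits(genome: Genome, n: int,
                               seed: int) -> list[tuple[str, int]]:
    """Length-weighted uniform background positions, away from edges."""
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    chroms = list(lengths)
    total = sum(lengths.values())
    weights = np.array([lengths[c] / total for c in chroms])
    pick = rng.choice(len(chroms), size=n, p=weights)
    out = []
    for ci in pick:
        chrom = chroms[ci]
        pos = int(rng.integers(500, lengths[chrom] - 500))
        out.append((chrom, pos))
    return out


def run_all(bundle_dir: str | Path, out_dir: str | Path, seed: int,
            config: RunConfig | None = None,
            acetyl_peaks_path: str | Path | None = None) -> dict:
    """Run the full analysis on a study bundle directory (see simulate_study).

    Writes report.json plus per-stage TSV tables under out_dir and returns
    the report dict.
    """
    bundle_dir = Path(bundle_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig()

    with open(bundle_dir / "manifest.json") as fh:
        manifest = json.load(fh)

    genome = read_fasta(bundle_dir / manifest["genome"])
    config_blob = json.dumps(
        {"config": config.to_dict(), "manifest": manifest, "seed": seed},
        sort_keys=True)
    report: dict = {
        "inputs": {"bundle": str(bundle_dir), "seed": seed,
                   "config_hash": hashlib.sha256(
                       config_blob.encode()).hexdigest()},
        "warnings": [],
    }

    # stage 1: two-caller consensus per factor
    consensus: dict[str, PeakSet] = {}
    tracks = {}
    for entry in manifest["factors"]:
        label = entry["label"]
        primary = read_peaks(bundle_dir / entry["peaks_primary"],
                             "narrowPeak", label=label)
        confirm = read_peaks(bundle_dir / entry["peaks_confirm"],
                             "narrowPeak", label=label + "_B")
        consensus[label] = peak_ops.consensus_peaks(primary, confirm)
        tracks[label] = read_tags(bundle_dir / entry["tags"], label=label)
        report.setdefault("consensus", {})[label] = {
            "n_primary": len(primary), "n_confirm": len(confirm),
            "n_consensus": len(consensus[label]),
        }

    factors = sorted(consensus)

    # stage 2: co-binding partition
    part = peak_ops.partition([consensus[f] for f in factors])
    venn = part.venn_table()
    _write_tsv(out_dir / "venn_counts.tsv", venn)
    report["venn"] = {row["category"]: row["n_regions"] for row in venn}

    # stage 3: summit distances for every shared factor pair
    report["summit_distance"] = {}
    for i, fa in enumerate(factors):
        for fb in factors[i + 1:]:
            shared = [r for r in part.regions
                      if fa in r.factors and fb in r.factors]
            if not shared:
                continue
            d = peak_ops.summit_distances(part, fa, fb)
            report["summit_distance"][f"{fa}+{fb}"] = {
                "n": len(d),
                "fraction_within_cutoff": peak_ops.fraction_within(
                    d, config.summit_dist_cutoff),
                "cutoff": config.summit_dist_cutoff,
            }

    # stage 4: motif fractions per category
    motif_rows: list[dict] = []
    for cat, regions in sorted(part.by_category().items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        rep_factor = sorted(cat)[0]
        summits = [(r.interval.chrom, r.summit(rep_factor)) for r in regions]
        for pattern in (CORE_MOTIF, BROAD_MOTIF):
            k, n, frac = motif_analysis.fraction_regions_with_motif(
                summits, genome, pattern, config.summit_motif_window_half)
            motif_rows.append({"category": "+".join(sorted(cat)),
                               "pattern": pattern, "k": k, "n": n,
                               "fraction": frac})
    _write_tsv(out_dir / "motif_fractions.tsv", motif_rows)
    report["motif_fractions"] = motif_rows

    # stage 5: permuted-core survey for the first factor vs background
    peak_summits = [(p.chrom, p.summit) for p in consensus[factors[0]]]
    if peak_summits:
        background = _sample_background_summits(
            genome, 10 * len(peak_summits),
            seed=_stage_seed(seed, "background"))
        survey, survey_consensus = motif_analysis.permuted_motif_survey(
            peak_summits, background, genome, CORE_MOTIF,
            window_half=config.summit_motif_window_half)
        _write_tsv(out_dir / "motif_survey.tsv",
                   [dataclasses.asdict(r) for r in survey])
        report["motif_survey"] = {
            "factor": factors[0],
            "top_variants": [r.variant for r in survey[:4]],
            "consensus": survey_consensus,
        }
    else:
        report["motif_survey"] = {}
        report["warnings"].append("survey stage: no consensus peaks")

    # stage 6: genome saturation of motif instances by bound regions
    all_bound = [r.interval for r in part.regions]
    report["saturation"] = {}
    for pattern in (CORE_MOTIF, BROAD_MOTIF):
        n_total, n_in, frac = motif_analysis.motif_binding_saturation(
            genome, pattern, all_bound)
        report["saturation"][pattern] = {
            "n_genome": n_total, "n_in_bound": n_in, "fraction": frac}

    # stage 7: flanking-base preference per factor
    report["flank_preference"] = {}
    for label in factors:
        summits = [(p.chrom, p.summit) for p in consensus[label]]
        try:
            profile = flanking_pref.flank_preference_analysis(
                summits, genome, CORE_MOTIF,
                window_total=config.summit_scan_window_total,
                flank_span=config.flank_span, n_reps=config.n_sim,
                sd_threshold=config.sd_threshold,
                seed=_stage_seed(seed, f"flank:{label}"))
        except ValueError as exc:
            report["warnings"].append(f"flank stage ({label}): {exc}")
            continue
        sig = [
            {"offset": profile.offsets[i], "base": flanking_pref.BASES[j],
             "z": float(profile.z[i, j])}
            for i, j in zip(*np.nonzero(profile.significant))
        ]
        report["flank_preference"][label] = {
            "n_observed": profile.n_observed,
            "significant": sig,
            "max_z": float(np.max(profile.z)),
        }
        flanking_pref.flank_matrix_export(profile).to_csv(
            out_dir / f"flank_matrix_{label}.tsv", sep="\t", index=False,
            float_format="%.6g")

    # stage 8: tag-density profiles
    report["tag_profiles"] = {}
    chrom_lengths = genome.lengths
    for label in factors:
        anchors = [(p.name or str(i), p.chrom, p.summit, "+")
                   for i, p in enumerate(consensus[label])]
        if not anchors:
            report["warnings"].append(f"profile stage ({label}): no peaks")
            continue
        fragments = tp.extend_tags(tracks[label], config.fragment_len,
                                   chrom_lengths)
        dm = tp.density_matrix(fragments, anchors, half_width=1000,
                               bin_size=config.profile_bin,
                               chrom_lengths=chrom_lengths)
        profile = tp.average_profile(dm)
        np.savetxt(out_dir / f"profile_{label}.tsv",
                   np.column_stack([dm.bin_centers(), profile]),
                   delimiter="\t", header="offset\tmean_density", fmt="%.6g",
                   comments="")
        central = profile[len(profile) // 2 - 1: len(profile) // 2 + 1].mean()
        report["tag_profiles"][label] = {
            "n_regions": dm.matrix.shape[0],
            "central_density": float(central),
            "argmax_bin_offset": float(dm.bin_centers()[int(np.argmax(profile))]),
        }
    # per-category central density for the first factor's track
    track0 = factors[0]
    fragments0 = tp.extend_tags(tracks[track0], config.fragment_len,
                                chrom_lengths)
    cat_density = {}
    for cat, regions in part.by_category().items():
        if track0 not in cat:
            continue
        anchors = [(f"r{i}", r.interval.chrom, r.summit(track0), "+")
                   for i, r in enumerate(regions)]
        dm = tp.density_matrix(fragments0, anchors, half_width=500,
                               bin_size=config.profile_bin,
                               chrom_lengths=chrom_lengths)
        prof = tp.average_profile(dm)
        mid = len(prof) // 2
        cat_density["+".join(sorted(cat))] = float(prof[mid - 1:mid + 1].mean())
    report["category_central_density"] = cat_density

    # stage 9: gene association and regulation tables
    genes = read_gene_models(bundle_dir / manifest["genes"])
    expr = read_expression_table(bundle_dir / manifest["expression"])
    regulation = classify_regulation(expr, config)
    reg_table = annotate_assoc.category_regulation_table(
        part, genes, regulation, window=config.tss_window)
    _write_tsv(out_dir / "regulation_table.tsv", reg_table.rows)
    report["regulation_table"] = reg_table.rows
    report["multi_category_genes"] = reg_table.multi_category_genes

    try:
        profiles = annotate_assoc.tss_group_profile(
            tracks[factors[0]], genes, regulation, half_width=1000,
            bin_size=config.profile_bin, fragment_len=config.fragment_len,
            chrom_lengths=chrom_lengths,
            seed=_stage_seed(seed, "control-genes"))
        report["tss_group_central"] = {
            name: float(prof[len(prof) // 2 - 1:len(prof) // 2 + 1].mean())
            for name, prof in profiles.items()
        }
    except ValueError as exc:
        report["warnings"].append(f"tss profile stage: {exc}")

    # stage 10: optional histone-acetylation co-association
    if acetyl_peaks_path is not None:
        acetyl = read_peaks(acetyl_peaks_path, "narrowPeak", label="acetyl")
        report["co_association"] = annotate_assoc.co_association_summary(
            list(acetyl), part, genome, CORE_MOTIF)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def report_hash(report: dict) -> str:
    return hashlib.sha256(
        json.dumps(report, sort_keys=True).encode()).hexdigest()


def _write_tsv(path: Path, rows: Sequence[dict]) -> None:
    if not rows:
        path.write_text("")
        return
    cols: list[str] = []
    for row in rows:
        for c in row:
            if c not in cols:
                cols.append(c)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c, "")) for c in cols) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
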