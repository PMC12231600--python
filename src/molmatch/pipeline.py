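"""End-to-end paired-platform comparison pipeline.

``run_all`` generates the synthetic experiment, renders both platforms'
alignment files, and runs preprocessing, dual annotation, cell calling, QC,
counting and all comparison statistics, returning every intermediate in a
``RunResult`` and (optionally) writing a run directory with the standard
text outputs plus a deterministic ``report.json``.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from molmatch import annotate, cell_qc, embed, quantify, render, report as report_mod
from molmatch.config import PipelineConfig, SimConfig
from molmatch.molecules import (TrueMolecule, generate_molecules,
                                generate_population, write_truth,
                                write_whitelist)
from molmatch.preprocess import (ReadRecord, dedup_long, dedup_short,
                                 group_by_tag, load_sam)
from molmatch.reference import ReferenceBundle, generate_reference, write_fasta, write_gtf


@dataclass
class RunResult:
    config: SimConfig
    pipe: PipelineConfig
    ref: ReferenceBundle
    molecules: list[TrueMolecule]
    whitelist: list[str]
    short_records: list[ReadRecord] = field(default_factory=list)
    long_records: list[ReadRecord] = field(default_factory=list)
    short_survivors: dict = field(default_factory=dict)
    long_survivors: dict = field(default_factory=dict)
    short_class: dict = field(default_factory=dict)
    isoforms: list = field(default_factory=list)
    classifications: dict = field(default_factory=dict)
    tag_to_isoform: dict = field(default_factory=dict)
    cells_short: set = field(default_factory=set)
    cells_long: set = field(default_factory=set)
    common_cells: list = field(default_factory=list)
    empty_partition: dict = field(default_factory=dict)
    sharing: quantify.TagSharing | None = None
    crosswalk: pd.DataFrame | None = None
    cm_short: quantify.CountMatrix | None = None
    cm_long_unfiltered: quantify.CountMatrix | None = None
    cm_long_filtered: quantify.CountMatrix | None = None
    de_unfiltered: pd.DataFrame | None = None
    de_filtered: pd.DataFrame | None = None
    strata_unfiltered: dict = field(default_factory=dict)
    strata_filtered: dict = field(default_factory=dict)
    pearson_unfiltered: float = float("nan")
    pearson_filtered: float = float("nan")
    ks: tuple[float, float] = (float("nan"), float("nan"))
    contamination: dict = field(default_factory=dict)
    embedding: embed.PairedEmbedding | None = None
    report: dict = field(default_factory=dict)


def mark_counted(groups: dict, ref: ReferenceBundle,
                 exon_overlap_frac: float = 0.5) -> None:
    """Set the per-read 'counted' flag the short-read dedup hierarchy needs:
    uniquely-mapped exonic reads assigned to exactly one gene."""
    for recs in groups.values():
        for r in recs:
            if not r.mapped or r.mapq != 255 or r.alignment_count != 1:
                continue
            region, _ = annotate.classify_short(r, ref, exon_overlap_frac)
            if region != "exonic":
                continue
            r.counted = len(annotate.assigned_genes(r, ref, exon_overlap_frac)) == 1


def simulate(config: SimConfig, outdir: Path) -> dict:
    """Generate and write the synthetic experiment; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = generate_reference(config)
    pop = generate_population(config, np.random.default_rng([config.seed, 0x300]))
    mols = generate_molecules(config, ref, pop)
    paths = {
        "fasta": outdir / "ref.fa", "gtf": outdir / "ref.gtf",
        "whitelist": outdir / "whitelist.txt", "truth": outdir / "truth.tsv",
        "short_sam": outdir / "short.sam", "long_sam": outdir / "long.sam",
        "arrays": outdir / "arrays.fa",
    }
    write_fasta(ref, paths["fasta"])
    write_gtf(ref, paths["gtf"])
    write_whitelist(pop, paths["whitelist"])
    write_truth(mols, paths["truth"])
    render.render_short_reads(mols, ref, config, paths["short_sam"])
    render.render_long_reads(mols, ref, config, paths["long_sam"],
                             paths["arrays"])
    return {"ref": ref, "population": pop, "molecules": mols, "paths": paths}


def run_all(config: SimConfig | None = None,
            pipe: PipelineConfig | None = None,
            outdir=None, write_outputs: bool = True) -> RunResult:
    config = config or SimConfig()
    pipe = pipe or PipelineConfig()

    tmp = None
    if outdir is None:
        tmp = tempfile.TemporaryDirectory()
        outdir = Path(tmp.name)
        write_outputs = False
    outdir = Path(outdir)

    try:
        sim = simulate(config, outdir)
        ref, pop, mols = sim["ref"], sim["population"], sim["molecules"]
        res = RunResult(config, pipe, ref, mols, pop.whitelist)

        # --- preprocessing -------------------------------------------------
        res.short_records = load_sam(sim["paths"]["short_sam"], "short")
        res.long_records = load_sam(sim["paths"]["long_sam"], "long")
        short_groups, _ = group_by_tag(res.short_records, pop.whitelist,
                                       pipe.barcode_prefix)
        long_groups, _ = group_by_tag(res.long_records, pop.whitelist,
                                      pipe.barcode_prefix)
        mark_counted(short_groups, ref, pipe.exon_overlap_frac)
        res.short_survivors = dedup_short(short_groups, config.seed)
        res.long_survivors = dedup_long(long_groups)

        # --- dual annotation ----------------------------------------------
        res.short_class = {
            key: annotate.classify_short(r, ref, pipe.exon_overlap_frac)
            for key, r in res.short_survivors.items()}
        long_mapped = [r for r in res.long_survivors.values() if r.mapped]
        res.isoforms = annotate.collapse_isoforms(
            long_mapped, pipe.end_tolerance_5p, pipe.end_tolerance_3p)
        res.classifications = annotate.classify_and_flag(
            res.isoforms, ref,
            pipe.intrapriming_window, pipe.intrapriming_a_frac,
            pipe.rt_repeat_len, pipe.rt_window, pipe.lcnc_min_coverage)
        res.tag_to_isoform = {t: iso.isoform_id for iso in res.isoforms
                              for t in iso.supporting_tags}

        # --- cell calling + QC ---------------------------------------------
        counts_short = _barcode_counts(res.short_survivors)
        counts_long = _barcode_counts(res.long_survivors)
        res.cells_short = cell_qc.call_cells_short(counts_short,
                                                   pipe.rescue_min_count)
        res.cells_long = cell_qc.knee_call(counts_long)
        res.common_cells = sorted(res.cells_short & res.cells_long)
        res.empty_partition = cell_qc.empty_droplet_call(
            counts_long, expected_cells=max(1, len(res.cells_short)),
            cap=pipe.empty_cap, quantile=pipe.empty_quantile,
            divisor=pipe.empty_divisor, min_dist=pipe.empty_min_dist)

        cell_of = {b: "high_rna" for b in pop.high_barcodes}
        cell_of.update({b: "low_rna" for b in pop.low_barcodes})
        cell_of.update({b: "ambient" for b in pop.ambient_barcodes})
        tagged_short = [r for recs in short_groups.values() for r in recs]
        _, per_cell, per_class, overall = cell_qc.tso_polya_contamination(
            tagged_short, config.tso_sequence, pipe.tso_max_mismatch,
            pipe.polya_run, pipe.polya_max_interrupt, cell_of)
        res.contamination = {"overall": overall,
                             "per_class": per_class.to_dict(orient="index")}

        # --- counting -------------------------------------------------------
        cells = res.common_cells
        res.cm_short = quantify.count_short(res.short_survivors, ref, cells,
                                            pipe.exon_overlap_frac)
        res.cm_long_unfiltered = quantify.count_long(
            res.long_survivors, res.classifications, res.tag_to_isoform, ref,
            cells, "unfiltered")
        res.cm_long_filtered = quantify.count_long(
            res.long_survivors, res.classifications, res.tag_to_isoform, ref,
            cells, "artefact_filtered")

        # --- comparisons ----------------------------------------------------
        truth_lengths = {m.tag_key: float(m.length) for m in mols}
        res.sharing = quantify.match_tags(res.short_survivors.keys(),
                                          res.long_survivors.keys(),
                                          truth_lengths)
        res.crosswalk = _build_crosswalk(res)

        cs = res.cm_short.protein_coding()
        cu = res.cm_long_unfiltered.protein_coding()
        cf = res.cm_long_filtered.protein_coding()
        res.pearson_unfiltered = quantify.pseudobulk_correlation(
            cs, cu, pipe.scale_factor)
        res.pearson_filtered = quantify.pseudobulk_correlation(
            cs, cf, pipe.scale_factor)
        res.de_unfiltered = quantify.de_by_platform(
            quantify.pseudo_bulk(cs), quantify.pseudo_bulk(cu),
            pipe.dispersion, pipe.lfc_threshold, pipe.fdr_threshold)
        res.de_filtered = quantify.de_by_platform(
            quantify.pseudo_bulk(cs), quantify.pseudo_bulk(cf),
            pipe.dispersion, pipe.lfc_threshold, pipe.fdr_threshold)
        meta = cs.gene_meta
        res.strata_unfiltered = quantify.stratify_by_length_gc(
            res.de_unfiltered, meta)
        res.strata_filtered = quantify.stratify_by_length_gc(
            res.de_filtered, meta)

        flagged_lengths, all_lengths = _length_samples(res)
        if flagged_lengths and all_lengths:
            res.ks = quantify.ks_length_bias(flagged_lengths, all_lengths)

        if len(cells) >= 3:
            res.embedding = embed.embed_pairs(
                cs, cu, pipe.n_hvg, pipe.n_pcs, pipe.embed_method, config.seed,
                pipe.scale_factor)

        res.report = _assemble_report(res)
        if write_outputs:
            _write_outputs(res, outdir)
        return res
    finally:
        if tmp is not None:
            tmp.cleanup()


def _barcode_counts(survivors: dict) -> dict[str, int]:
    counts: dict[str, int] = {}
    for key in survivors:
        bc = key[:16]
        counts[bc] = counts.get(bc, 0) + 1
    return counts


def _build_crosswalk(res: RunResult) -> pd.DataFrame:
    rows = []
    for key in sorted(res.sharing.shared):
        region, _mapping = res.short_class[key]
        iso_id = res.tag_to_isoform.get(key)
        if iso_id is None:
            long_class = "discarded"
        else:
            long_class = res.classifications[iso_id].category
        srec = res.short_survivors[key]
        lrec = res.long_survivors[key]
        same_loc = bool(srec.mapped and lrec.mapped
                        and srec.chrom == lrec.chrom
                        and srec.start < lrec.end and lrec.start < srec.end)
        rows.append({"tag": key, "short_class": region,
                     "long_class": long_class, "same_location": same_loc})
    table = pd.DataFrame(rows, columns=["tag", "short_class", "long_class",
                                        "same_location"])
    return annotate.crosswalk(table)


def _length_samples(res: RunResult):
    flagged, universe = [], []
    for iso in res.isoforms:
        cls = res.classifications[iso.isoform_id]
        for t in iso.supporting_tags:
            r = res.long_survivors.get(t)
            if r is None:
                continue
            universe.append(r.aligned_length)
            if cls.artefact_flags:
                flagged.append(r.aligned_length)
    return flagged, universe


def _category_accounting(res: RunResult) -> dict:
    out: dict = {}
    for cat in annotate.ISO_CATEGORIES:
        isos = [i for i in res.isoforms
                if res.classifications[i.isoform_id].category == cat]
        kept = [i for i in isos
                if not res.classifications[i.isoform_id].artefact_flags]
        out[cat] = {
            "isoforms_unfiltered": len(isos),
            "isoforms_filtered": len(kept),
            "reads_unfiltered": int(sum(i.coverage for i in isos)),
            "reads_filtered": int(sum(i.coverage for i in kept)),
        }
    flags: dict[str, int] = {}
    flag_reads: dict[str, int] = {}
    for iso in res.isoforms:
        for f in res.classifications[iso.isoform_id].artefact_flags:
            flags[f] = flags.get(f, 0) + 1
            flag_reads[f] = flag_reads.get(f, 0) + iso.coverage
    out["artefacts"] = {"isoforms": flags, "reads": flag_reads}
    return out


def _assemble_report(res: RunResult) -> dict:
    sharing = res.sharing
    sections = {
        "config": {"sim": res.config.to_dict(), "pipeline": res.pipe.to_dict()},
        "generation": {
            "n_molecules": len(res.molecules),
            "n_genes": len(res.ref.genes),
            "artefact_counts": _value_counts(m.artefact_label
                                             for m in res.molecules),
        },
        "preprocessing": {
            "n_short_records": len(res.short_records),
            "n_long_records": len(res.long_records),
            "n_short_tags": len(res.short_survivors),
            "n_long_tags": len(res.long_survivors),
        },
        "tag_sharing": {
            "n_shared": len(sharing.shared),
            "n_short_only": len(sharing.short_only),
            "n_long_only": len(sharing.long_only),
            "n_union": sharing.n_union,
            "frac_long_shared": (len(sharing.shared)
                                 / max(1, len(sharing.shared)
                                       + len(sharing.long_only))),
            "length_bins": sharing.bin_table.set_index("bin").to_dict(
                orient="index"),
        },
        "crosswalk": res.crosswalk,
        "cell_calling": {
            "n_cells_short": len(res.cells_short),
            "n_cells_long": len(res.cells_long),
            "n_common": len(res.common_cells),
            "empty_partition": _value_counts(res.empty_partition.values()),
        },
        "qc": res.contamination,
        "counting": {
            "total_short": res.cm_short.total if res.cm_short else None,
            "total_long_unfiltered": (res.cm_long_unfiltered.total
                                      if res.cm_long_unfiltered else None),
            "total_long_filtered": (res.cm_long_filtered.total
                                    if res.cm_long_filtered else None),
            "categories": _category_accounting(res),
        },
        "differential_expression": {
            "pearson_unfiltered": res.pearson_unfiltered,
            "pearson_filtered": res.pearson_filtered,
            "unfiltered": {
                "n_higher_short": int((res.de_unfiltered["direction"]
                                       == "higher_A").sum()),
                "n_higher_long": int((res.de_unfiltered["direction"]
                                      == "higher_B").sum()),
                "strata": res.strata_unfiltered,
            },
            "filtered": {
                "n_higher_short": int((res.de_filtered["direction"]
                                       == "higher_A").sum()),
                "n_higher_long": int((res.de_filtered["direction"]
                                      == "higher_B").sum()),
                "strata": res.strata_filtered,
            },
        },
        "length_bias": {"ks_statistic": res.ks[0], "ks_pvalue": res.ks[1]},
        "embedding": ({
            "provenance": res.embedding.provenance,
            "median_paired_distance": float(res.embedding.distances.median()),
            "max_paired_distance": float(res.embedding.distances.max()),
        } if res.embedding is not None else None),
    }
    return report_mod.build_report(sections)


def _value_counts(it) -> dict:
    out: dict[str, int] = {}
    for v in it:
        out[str(v)] = out.get(str(v), 0) + 1
    return out


def _write_outputs(res: RunResult, outdir: Path) -> None:
    report_mod.write_report(res.report, outdir / "report.json")
    res.crosswalk.to_csv(outdir / "crosswalk.tsv", sep="\t")
    res.de_unfiltered.to_csv(outdir / "de_unfiltered.tsv", sep="\t")
    res.de_filtered.to_csv(outdir / "de_filtered.tsv", sep="\t")
    for name, cm in (("short", res.cm_short),
                     ("long_unfiltered", res.cm_long_unfiltered),
                     ("long_filtered", res.cm_long_filtered)):
        if cm is not None:
            cm.counts.to_csv(outdir / f"counts_{name}.tsv", sep="\t")
            _write_mtx(cm, outdir, name)
    with open(outdir / "dedup.tsv", "w") as fh:
        fh.write("tag_key\tplatform\tsurvivor_query_name\treason_code\n")
        for platform, survivors in (("short", res.short_survivors),
                                    ("long", res.long_survivors)):
            for key in sorted(survivors):
                r = survivors[key]
                reason = ("counted" if r.counted
                          else "mapped" if r.mapped else "unmapped")
                fh.write(f"{key}\t{platform}\t{r.query_name}\t{reason}\n")
    iso_rows = []
    for iso in res.isoforms:
        cls = res.classifications[iso.isoform_id]
        iso_rows.append({
            "isoform_id": iso.isoform_id, "chrom": iso.chrom,
            "strand": iso.strand,
            "chain": ";".join(f"{a}-{b}" for a, b in iso.chain),
            "start": iso.start, "end": iso.end, "coverage": iso.coverage,
            "category": cls.category,
            "flags": ",".join(sorted(cls.artefact_flags)),
        })
    pd.DataFrame(iso_rows).to_csv(outdir / "isoforms.tsv", sep="\t",
                                  index=False)


def _write_mtx(cm, outdir: Path, name: str) -> None:
    from scipy import io as spio
    from scipy.sparse import csr_matrix
    spio.mmwrite(str(outdir / f"counts_{name}.mtx"),
                 csr_matrix(cm.counts.to_numpy()))
    (outdir / f"genes_{name}.tsv").write_text(
        "".join(g + "\n" for g in cm.counts.index))
    (outdir / f"barcodes_{name}.tsv").write_text(
        "".join(c + "\n" for c in cm.counts.columns))


def write_plots(res: RunResult, outdir) -> list:
    """Optional diagnostic plots: barcode-rank curves, per-bin tag sharing
    and the paired-distance distribution."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(5, 4))
    for survivors, label in ((res.short_survivors, "short"),
                             (res.long_survivors, "long")):
        counts = sorted(_barcode_counts(survivors).values(), reverse=True)
        ax.loglog(range(1, len(counts) + 1), counts, label=label)
    ax.set_xlabel("barcode rank")
    ax.set_ylabel("UMI count")
    ax.legend()
    fig.savefig(outdir / "barcode_rank.png", dpi=120)
    plt.close(fig)
    written.append(outdir / "barcode_rank.png")

    if res.sharing is not None and len(res.sharing.bin_table):
        fig, ax = plt.subplots(figsize=(5, 4))
        tbl = res.sharing.bin_table
        ax.bar(tbl["bin"], tbl["frac_shared"])
        ax.set_xlabel("log2 molecule length bin")
        ax.set_ylabel("fraction of long-read tags shared")
        fig.savefig(outdir / "length_bin_sharing.png", dpi=120)
        plt.close(fig)
        written.append(outdir / "length_bin_sharing.png")

    if res.embedding is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.hist(res.embedding.distances.to_numpy(), bins=30)
        ax.set_xlabel("paired-cell distance")
        ax.set_ylabel("cells")
        fig.savefig(outdir / "paired_distances.png", dpi=120)
        plt.close(fig)
        written.append(outdir / "paired_distances.png")
    return written
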