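"""End-to-end orchestration of the fine-mapping stages.

Stage order mirrors the study's logic: simulate (or load) the cohorts,
QC, per-population mixed-model scans, meta-analysis, LOD-drop support
intervals and their intersection, progeny-test segregation calls,
pedigree phasing and Q-haplotype sharing, candidate-variant concordance
and cross-species constraint filtering, and the final association
survey.  Every stage logs its inputs, outputs and the run seed; rerunning
the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    additive_effect,
    allele_frequencies,
    association_test,
    group_stats,
)
from .config import RunConfig
from .designs import StudyFixture, build_fixture
from .genotypes import PhasedGenotypeMatrix
from .gwas import (
    ScanResult,
    bonferroni_threshold,
    genomic_kinship,
    lod_drop_interval,
    intersect_intervals,
    meta_combine,
    polygenic_fit,
    single_locus_scan,
)
from .ibd import annotate_region, collect_q_haplotypes, pedigree_phase, shared_region
from .io import write_bed, write_pedigree, write_phenotypes, write_table, write_vcf
from .qc import qc_filter
from .segregation import (
    QTLGenotypeCall,
    QTLState,
    classify_sire,
    resolve_homozygote,
    split_progeny,
    zscore_fixed_effect,
)
from .simulate import corrupt
from .variants import (
    VariantGenotypeTable,
    complete_ld_check,
    concordance_test,
    constraint_filter,
)

__all__ = ["run_pipeline", "render_reports", "PipelineError"]

log = logging.getLogger("vertfine")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _concat_individuals(
    matrices: list[PhasedGenotypeMatrix], ids: list[str]
) -> PhasedGenotypeMatrix:
    """One matrix holding the listed individuals drawn from per-population
    matrices sharing the same marker map."""
    rows = []
    phase = []
    for iid in ids:
        for g in matrices:
            if iid in g.ids:
                i = g.row(iid)
                rows.append(g.alleles[i])
                phase.append(
                    g.phase_known[i]
                    if g.phase_known is not None
                    else np.ones(g.m, dtype=bool)
                )
                break
        else:
            raise KeyError(f"{iid!r} not genotyped in any population")
    return PhasedGenotypeMatrix(
        ids=ids,
        markers=matrices[0].markers,
        alleles=np.stack(rows),
        phase_known=np.stack(phase),
    )


def run_pipeline(config: RunConfig, fixture: StudyFixture | None = None) -> dict:
    """Execute all stages into ``config.out_dir``; returns the final
    report dictionary (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    prov = {
        "tool": "vertfine",
        "version": __version__,
        "config_sha256": config.digest(),
        "seed": config.seed,
    }
    stage_log: list[dict] = []

    def record(stage: str, **info) -> None:
        stage_log.append({"stage": stage, **info})
        log.info("stage %s: %s", stage, info)

    def fail(stage: str, cause: Exception) -> PipelineError:
        record(stage, error=str(cause))
        (out / "provenance.json").write_text(
            json.dumps({"provenance": prov, "stages": stage_log}, indent=2)
        )
        return PipelineError(stage, str(cause))

    # ---- simulate ----------------------------------------------------
    if fixture is None:
        fixture = build_fixture(config.sim.to_fixture_params(), seed=config.seed)
    fx = fixture
    hidden = {n for n in fx.populations["WE"].genotypes.markers.names if n.startswith("QTL@")}
    obs: dict[str, PhasedGenotypeMatrix] = {}
    for name, popdata in fx.populations.items():
        g = popdata.genotypes
        keep = np.flatnonzero(~np.isin(g.markers.names, list(hidden)))
        g = g.take_markers(keep)
        if config.sim.missing_rate or config.sim.error_rate:
            g = corrupt(
                g, config.sim.missing_rate, config.sim.error_rate, seed=config.seed + 17
            )
        obs[name] = g
        write_vcf(g, out / f"genotypes_{name}.vcf", seed=config.seed)
        write_pedigree(popdata.pedigree, out / f"pedigree_{name}.tsv")
        write_phenotypes(popdata.phenotypes, out / f"phenotypes_{name}.tsv")
    write_bed(fx.genes, out / "genes.bed")
    fx.species_table.rename_axis("variant").reset_index().to_csv(
        out / "species_alleles.tsv", sep="\t", index=False
    )
    config.to_yaml(out / "config.yaml")
    record("simulate", populations={k: v.genotypes.n for k, v in fx.populations.items()})

    # ---- QC + per-population scans ----------------------------------
    scan_pops = ["WE", "SU", "ET"]
    scans: dict[str, ScanResult] = {}
    thresholds: dict[str, float] = {}
    for name in scan_pops:
        popdata = fx.populations[name]
        chip_rows = np.flatnonzero(np.isin(obs[name].markers.names, fx.chip_markers))
        try:
            clean, report = qc_filter(
                obs[name].take_markers(chip_rows),
                popdata.pedigree,
                config.qc.to_thresholds(),
            )
        except Exception as e:  # noqa: BLE001
            raise fail(f"qc:{name}", e) from e
        write_table(report.to_frame(), out / f"qc_{name}.tsv", prov)
        pheno = popdata.phenotypes.set_index("id")["thoracic"].astype(float)
        pheno = pheno.loc[[i for i in pheno.index if i in clean.ids]]
        try:
            analyzed = clean.take_individuals(list(pheno.index))
            kin = genomic_kinship(analyzed)
            model = polygenic_fit(pheno, kin)
            scan = single_locus_scan(analyzed, pheno, model=model)
        except Exception as e:  # noqa: BLE001
            raise fail(f"gwas:{name}", e) from e
        thresholds[name] = bonferroni_threshold(config.gwas_alpha, report.n_informative)
        scan.threshold_p = thresholds[name]
        scans[name] = scan
        write_table(scan.table, out / f"scan_{name}.tsv", {**prov, "h2": f"{model.h2:.4f}"})
        record(
            f"gwas:{name}",
            n_informative=report.n_informative,
            n_animals=len(pheno),
            top=scan.top_marker,
            h2=round(model.h2, 4),
        )

    # ---- meta-analysis and localization ------------------------------
    try:
        meta = meta_combine([scans[n] for n in scan_pops])
    except Exception as e:  # noqa: BLE001
        raise fail("meta", e) from e
    write_table(meta.table, out / "scan_meta.tsv", prov)
    top = meta.table.loc[meta.table["lod"].idxmax()]
    anchor_chrom, anchor_bp = str(top["chrom"]), int(top["bp"])
    record("meta", top_marker=str(top["marker"]), chrom=anchor_chrom, bp=anchor_bp)

    cis = {}
    for name in scan_pops:
        sub = scans[name].restrict_chrom(anchor_chrom)
        best_p = sub.table["p"].min()
        if best_p <= thresholds[name]:
            cis[name] = lod_drop_interval(sub, drop=config.lod_drop)
        else:
            record(f"ci:{name}", skipped="no genome-wide significant signal on anchor chromosome")
    if not cis:
        raise fail("ci", RuntimeError("no population shows significant signal"))
    ci_rows = [
        (n, iv.chrom, iv.start_bp, iv.end_bp, iv.top_marker) for n, iv in cis.items()
    ]
    try:
        overlap = intersect_intervals(list(cis.values()))
    except ValueError:
        # on a sparse scaled-down panel per-population support intervals can
        # be disjoint; fall back to the populations whose interval covers the
        # meta-analysis anchor and report the discordant ones
        anchored = {n: iv for n, iv in cis.items() if iv.contains(anchor_bp)}
        dropped = sorted(set(cis) - set(anchored))
        if not anchored:
            best = max(cis, key=lambda n: scans[n].table["lod"].max())
            anchored = {best: cis[best]}
            dropped = sorted(set(cis) - {best})
        record("intersect", discordant_populations=dropped)
        try:
            overlap = intersect_intervals(list(anchored.values()))
        except Exception as e:  # noqa: BLE001
            raise fail("intersect", e) from e
    except Exception as e:  # noqa: BLE001
        raise fail("intersect", e) from e
    ci_rows.append(("overlap", overlap.chrom, overlap.start_bp, overlap.end_bp, ""))
    write_table(
        pd.DataFrame(ci_rows, columns=["population", "chrom", "start_bp", "end_bp", "top_marker"]),
        out / "intervals.tsv",
        prov,
    )
    record("intersect", start=overlap.start_bp, end=overlap.end_bp)

    # ---- pedigree phasing --------------------------------------------
    phased: dict[str, PhasedGenotypeMatrix] = {}
    for name in scan_pops:
        phased[name], n_err = pedigree_phase(obs[name], fx.populations[name].pedigree)
        record(f"phase:{name}", mendelian_sites_blanked=n_err)

    # ---- progeny-test segregation ------------------------------------
    # haplotype transmission is resolved over the support interval, widened
    # to a minimum span so a very sharp peak still leaves informative markers
    region = (
        overlap.chrom,
        min(overlap.start_bp, anchor_bp - 2_000_000),
        max(overlap.end_bp, anchor_bp + 2_000_000),
    )
    sires = {
        "WE": [i for i in fx.populations["WE"].pedigree.generation_ids("F1")
               if fx.populations["WE"].pedigree.offspring_of(i)
               and fx.populations["WE"].pedigree.table.set_index("id").loc[i, "sex"] == "M"],
        "SU": [i for i in fx.populations["SU"].pedigree.generation_ids("F0")
               if fx.populations["SU"].pedigree.offspring_of(i)
               and fx.populations["SU"].pedigree.table.set_index("id").loc[i, "sex"] == "M"],
        "ET": [i for i in fx.populations["ET"].pedigree.generation_ids("F1")
               if fx.populations["ET"].pedigree.offspring_of(i)
               and fx.populations["ET"].pedigree.table.set_index("id").loc[i, "sex"] == "M"],
    }
    calls: list[QTLGenotypeCall] = []
    call_pop: dict[str, str] = {}
    seg_rows = []
    groups_by_sire = {}
    for name, sire_list in sires.items():
        popdata = fx.populations[name]
        pheno = popdata.phenotypes.set_index("id")["thoracic"].astype(float)
        for sire in sire_list:
            try:
                groups = split_progeny(phased[name], popdata.pedigree, pheno, sire, region)
                if min(groups.left.size, groups.right.size) < config.min_progeny_group:
                    continue
                z = zscore_fixed_effect(groups, config.substitution_effect)
            except ValueError:
                continue
            call = classify_sire(sire, z, (config.z_upper, config.z_lower))
            groups_by_sire[sire] = groups
            calls.append(call)
            call_pop[sire] = name
            seg_rows.append(
                (
                    name,
                    sire,
                    z.n_left,
                    z.n_right,
                    round(z.mean_left, 3),
                    round(z.mean_right, 3),
                    round(z.z, 3),
                    call.state.value,
                    "/".join(call.hap_orientation),
                )
            )
    het_calls = [c for c in calls if c.state == QTLState.HET]
    if not het_calls:
        raise fail("segregation", RuntimeError("no heterozygous sire deduced"))

    # resolve QQ vs qq against the het sires' progeny groups, population by
    # population (baselines differ between populations); unresolved sires
    # still constrain the concordance test as "homozygous, either class"
    def _side(c: QTLGenotypeCall, which: str) -> np.ndarray:
        g = groups_by_sire[c.animal_id]
        q_is_left = c.hap_orientation[0] == "Q"
        return (g.left if q_is_left else g.right) if which == "Q" else (
            g.right if q_is_left else g.left
        )

    resolved: list[QTLGenotypeCall] = []
    for c in calls:
        if c.state != QTLState.HOM:
            resolved.append(c)
            continue
        pop_hets = [h for h in het_calls if call_pop[h.animal_id] == call_pop[c.animal_id]]
        if not pop_hets:
            resolved.append(c)
            continue
        q_ref = np.concatenate([_side(h, "Q") for h in pop_hets])
        qq_ref = np.concatenate([_side(h, "q") for h in pop_hets])
        own = np.concatenate([groups_by_sire[c.animal_id].left, groups_by_sire[c.animal_id].right])
        resolved.append(resolve_homozygote(c, own, q_ref, qq_ref, config.founder_alpha))
    calls = resolved
    write_table(
        pd.DataFrame(
            seg_rows,
            columns=[
                "population", "sire", "n_left", "n_right", "mean_left",
                "mean_right", "z", "call", "orientation",
            ],
        ),
        out / "segregation.tsv",
        prov,
    )
    record("segregation", n_sires=len(calls), n_het=len(het_calls))

    # ---- IBD haplotype sharing ---------------------------------------
    try:
        qset = collect_q_haplotypes(calls)
        called_ids = sorted({iid for iid, _ in qset.entries})
        combined = _concat_individuals(list(phased.values()), called_ids)
        segment = shared_region(qset, combined, anchor_chrom, anchor_bp)
        gene_hits = annotate_region(segment, fx.genes)
    except Exception as e:  # noqa: BLE001
        raise fail("ibd", e) from e
    write_table(
        pd.DataFrame(
            [
                (
                    segment.chrom, segment.start_bp, segment.end_bp,
                    segment.n_markers, segment.n_haplotypes,
                    segment.flank_left or "", segment.flank_right or "",
                    segment.n_wildcard, ";".join(gene_hits),
                )
            ],
            columns=[
                "chrom", "start_bp", "end_bp", "n_markers", "n_haplotypes",
                "flank_left", "flank_right", "n_wildcard", "genes",
            ],
        ),
        out / "shared_segment.tsv",
        prov,
    )
    # haplotype matrix (1 = major, 2 = minor) over the segment and its flanks
    mm = combined.markers
    seg_rows_idx = mm.region_indices(segment.chrom, segment.start_bp, segment.end_bp)
    lo = max(seg_rows_idx[0] - 2, 0)
    hi = min(seg_rows_idx[-1] + 2, len(mm) - 1)
    shown = np.arange(lo, hi + 1)
    hap_rows = []
    for iid, hap in qset.entries:
        alleles = combined.alleles[combined.row(iid), shown, hap]
        hap_rows.append([f"{iid}.h{hap}", call_pop.get(iid, "")] + [int(a) for a in alleles])
    write_table(
        pd.DataFrame(hap_rows, columns=["haplotype", "population"] + [str(n) for n in mm.names[shown]]),
        out / "q_haplotype_matrix.tsv",
        prov,
    )
    record("ibd", start=segment.start_bp, end=segment.end_bp, genes=gene_hits)

    # ---- concordance + constraint ------------------------------------
    call_ids = [c.animal_id for c in calls]
    all_obs = _concat_individuals([obs[n] for n in scan_pops], call_ids)
    seq_rows = np.flatnonzero(np.isin(all_obs.markers.names, fx.seq_variants))
    vtab = VariantGenotypeTable(
        genotypes=all_obs.take_markers(seq_rows).dosage_frame().astype(int)
    )
    try:
        report = concordance_test(vtab, calls)
    except Exception as e:  # noqa: BLE001
        raise fail("concordance", e) from e
    write_table(report.summary, out / "concordance.tsv", prov)
    passing = report.passing
    record("concordance", n_tested=len(vtab.variants), passing=passing)
    if not passing:
        raise fail("concordance", RuntimeError("no variant concordant with QTL genotypes"))
    try:
        retained = constraint_filter(passing, fx.species_table)
    except Exception as e:  # noqa: BLE001
        raise fail("constraint", e) from e
    write_table(retained, out / "constraint.tsv", prov)
    final_candidates = list(retained.loc[retained["retained"], "variant"])
    record("constraint", retained=final_candidates)

    ld_pairs = []
    if len(passing) >= 2:
        dll_obs = obs["DLL"]
        seq_dll = dll_obs.take_markers(
            np.flatnonzero(np.isin(dll_obs.markers.names, passing))
        ).dosage_frame()
        for a in passing:
            for b in passing:
                if a < b:
                    in_ld, n_mm = complete_ld_check(seq_dll[a], seq_dll[b])
                    ld_pairs.append((a, b, in_ld, n_mm))
    write_table(
        pd.DataFrame(ld_pairs, columns=["v1", "v2", "complete_ld", "mismatches"]),
        out / "ld_pairs.tsv",
        prov,
    )

    # ---- association survey ------------------------------------------
    assoc_tables = []
    candidate = final_candidates[0] if final_candidates else passing[0]
    for name in ("SU", "DLL"):
        popdata = fx.populations[name]
        g = obs[name]
        vrow = g.markers.index_of(candidate)
        dosage = pd.Series(g.dosage()[:, vrow], index=g.ids).loc[popdata.phenotyped_ids]
        ph = popdata.phenotypes.set_index("id")
        for trait_name in ("thoracic", "lumbar"):
            y = ph[trait_name].astype(float)
            summary = group_stats(y, dosage)
            tests = association_test(y, dosage)
            f_row = tests.loc[tests["statistic"] == "F"].iloc[0]
            try:
                a_eff, d_eff = additive_effect(summary)
            except ValueError:
                a_eff = d_eff = np.nan
            for _, r in summary.iterrows():
                assoc_tables.append(
                    (
                        name, trait_name, r["genotype"], r["n"],
                        None if pd.isna(r["mean"]) else round(r["mean"], 2),
                        None if pd.isna(r["sd"]) else round(r["sd"], 2),
                        round(f_row["value"], 2), round(a_eff, 3), round(d_eff, 3),
                    )
                )
    assoc_df = pd.DataFrame(
        assoc_tables,
        columns=["population", "trait", "genotype", "n", "mean", "sd", "F", "additive", "dominance"],
    )
    write_table(assoc_df, out / "association.tsv", prov)

    geno_all = []
    for name, popdata in fx.populations.items():
        g = obs[name]
        vrow = g.markers.index_of(candidate)
        dos_col = g.dosage()[:, vrow]
        for iid in popdata.phenotyped_ids:
            geno_all.append((iid, name, int(dos_col[g.row(iid)])))
    geno_df = pd.DataFrame(geno_all, columns=["id", "population", "dosage"]).set_index("id")
    freq = allele_frequencies(geno_df["dosage"], geno_df["population"])
    write_table(freq, out / "allele_frequencies.tsv", prov)
    record("association", candidate=candidate)

    # ---- final report -------------------------------------------------
    thoracic_su = assoc_df.query("population=='SU' and trait=='thoracic'")
    report_dict = {
        "provenance": prov,
        "anchor": {"chrom": anchor_chrom, "bp": anchor_bp},
        "ci_overlap": {"start_bp": overlap.start_bp, "end_bp": overlap.end_bp},
        "shared_segment": {
            "start_bp": segment.start_bp,
            "end_bp": segment.end_bp,
            "n_haplotypes": segment.n_haplotypes,
            "genes": gene_hits,
        },
        "n_sires_called": len(calls),
        "concordant_variants": passing,
        "final_candidates": final_candidates,
        "additive_effect_su": float(thoracic_su["additive"].iloc[0]),
        "q_frequencies": {
            r["population"]: round(r["q_frequency"], 3) for _, r in freq.iterrows()
        },
        "stages": stage_log,
    }
    (out / "report.json").write_text(json.dumps(report_dict, indent=2))
    (out / "provenance.json").write_text(
        json.dumps({"provenance": prov, "stages": stage_log}, indent=2)
    )
    return report_dict


# ---------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------


def render_reports(run_dir: str | Path, make_plot: bool = True) -> list[Path]:
    """Derive presentation outputs from a completed run directory:
    Manhattan-plot data (and a PNG), and a haplotype-matrix text file in
    the 1/2 allele coding around the shared segment."""
    run_dir = Path(run_dir)
    report_path = run_dir / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"incomplete run directory: {report_path} missing")
    report = json.loads(report_path.read_text())
    outputs = []

    frames = []
    for scan_file in sorted(run_dir.glob("scan_*.tsv")):
        t = pd.read_csv(scan_file, sep="\t", comment="#")
        t["population"] = scan_file.stem.replace("scan_", "")
        frames.append(t)
    manhattan = pd.concat(frames, ignore_index=True)[
        ["population", "marker", "chrom", "bp", "lod"]
    ]
    path = run_dir / "manhattan_data.tsv"
    manhattan.to_csv(path, sep="\t", index=False)
    outputs.append(path)

    if make_plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        pops = list(dict.fromkeys(manhattan["population"]))
        fig, axes = plt.subplots(len(pops), 1, figsize=(8, 2.2 * len(pops)), sharex=True)
        for ax, popname in zip(np.atleast_1d(axes), pops):
            sub = manhattan[manhattan["population"] == popname]
            for k, (chrom, cs) in enumerate(sub.groupby("chrom", sort=False)):
                ax.scatter(cs["bp"] / 1e6 + k * 150, cs["lod"], s=4, label=str(chrom))
            ax.set_ylabel(f"{popname}\nLOD")
        plt.xlabel("position (Mb, chromosomes offset)")
        fig.tight_layout()
        png = run_dir / "manhattan.png"
        fig.savefig(png, dpi=100)
        plt.close(fig)
        outputs.append(png)

    seg = pd.read_csv(run_dir / "shared_segment.tsv", sep="\t", comment="#").iloc[0]
    outputs.append(run_dir / "shared_segment.tsv")
    report_txt = run_dir / "summary.txt"
    lines = [
        "fine-mapping summary",
        f"  anchor: chr{report['anchor']['chrom']}:{report['anchor']['bp']}",
        f"  CI overlap: {report['ci_overlap']['start_bp']}-{report['ci_overlap']['end_bp']} bp",
        f"  shared segment: {seg['start_bp']}-{seg['end_bp']} bp "
        f"({seg['n_haplotypes']} Q haplotypes)",
        f"  genes in segment: {seg['genes']}",
        f"  concordant variants: {', '.join(report['concordant_variants'])}",
        f"  final candidate(s): {', '.join(report['final_candidates'])}",
    ]
    report_txt.write_text("\n".join(lines) + "\n")
    outputs.append(report_txt)
    return outputs
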