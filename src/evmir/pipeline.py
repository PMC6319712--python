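"""End-to-end orchestration: simulate/load through classify and motif scan.

Stage order mirrors the analysis it reproduces: quantify counts to TPM,
apply the detection rule, test cell lysates against each other, test each
EV subtype against its parental lysate, partition the detected sets,
screen for cell-silent EV cargo, build a signature, classify a
tumour/normal panel, and scan precursors for sorting motifs.  A manifest
records seed, thresholds and completed stages; re-running a config gives
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (build_signature, evaluate_classifier, predict_samples,
                       select_features)
from .diffexpr import (Contrast, classify_dysregulated, estimate_dispersion,
                       nb_exact_test, tmm_factors)
from .distribution import (cell_silent_ev_screen, cross_cellline_overlap,
                           ev_enrichment_call, venn_partition)
from .io import (PipelineConfig, read_count_table, read_fasta, read_panel,
                 write_count_matrix, write_expression, write_fasta, write_json,
                 write_panel, write_truth)
from .motif import scan_motif
from .quantify import (CountMatrix, average_replicates, compartment_grouping,
                       compute_tpm, detect_features)
from .synthetic import (generate_count_matrix, generate_precursor_set,
                        generate_tumour_panel)

logger = logging.getLogger(__name__)

#: the nine analysis stages, in execution order (input acquisition --
#: simulation or loading -- happens before stage 1 and is not a stage)
STAGE_NAMES = ("quantify", "detect", "de_cell_lines", "ev_enrichment",
               "distribution", "cell_silent", "signature", "classify", "motif")


def run_de_contrast(cm: CountMatrix, group_a: list[str], group_b: list[str],
                    features: list[str] | None = None,
                    log2fc_cut: float = 1.0, p_cut: float = 0.05,
                    fdr_cut: float = 0.05) -> pd.DataFrame:
    """TMM -> dispersion -> exact test -> BH -> calls, for one contrast."""
    sub = cm.counts[group_a + group_b]
    if features is not None:
        sub = sub.loc[[f for f in sub.index if f in set(features)]]
    sub = sub.loc[sub.sum(axis=1) > 0]
    sub_cm = CountMatrix(counts=sub, libraries=cm.libraries.loc[group_a + group_b],
                         passenger=cm.passenger)
    factors = tmm_factors(sub_cm)
    contrast = Contrast(counts=sub_cm, group_a=group_a, group_b=group_b,
                        factors=factors)
    contrast.dispersion = estimate_dispersion(contrast)
    result = nb_exact_test(contrast)
    result["call"] = classify_dysregulated(result, log2fc_cut=log2fc_cut,
                                           p_cut=p_cut, fdr_cut=fdr_cut)
    return result


def _write_de(result: pd.DataFrame, path: Path) -> None:
    result.to_csv(path, sep="\t", index_label="feature", float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle under config.outdir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "thresholds": {"tpm_detect": config.tpm_detect,
                                     "log2fc": config.log2fc, "p": config.p,
                                     "fdr": config.fdr,
                                     "alt_fold_change": config.alt_fold_change},
                      "stages": []}
    bundle: dict = {}

    def stage(name: str):
        logger.info("[%s] running", name)
        manifest["stages"].append(name)

    try:
        # 0. counts: simulate or load (input acquisition, not a stage) ----
        if config.counts_path:
            cm, truth = read_count_table(config.counts_path), None
        else:
            sim = config.simulation
            if sim.seed != config.seed:
                sim = type(sim)(**{**asdict_sim(sim), "seed": config.seed})
            cm, truth = generate_count_matrix(sim)
            write_count_matrix(cm, out / "counts.tsv")
            write_truth(truth, out / "truth.json")
        bundle["counts"], bundle["truth"] = cm, truth

        # 1. TPM ----------------------------------------------------------
        stage("quantify")
        expr = compute_tpm(cm)
        grouping = compartment_grouping(cm)
        mean_expr = average_replicates(expr, grouping)
        write_expression(mean_expr, out / "tpm_mean.tsv")
        bundle["expr"], bundle["mean_expr"] = expr, mean_expr

        # 3. detection ----------------------------------------------------
        stage("detect")
        detection = detect_features(expr, grouping, threshold=config.tpm_detect)
        detection.detected.to_csv(out / "detected.tsv", sep="\t", index_label="feature")
        bundle["detection"] = detection

        lines = sorted(cm.libraries["cell_line"].unique())
        if len(lines) != 2:
            raise ValueError(f"pipeline expects exactly two cell lines, found {lines}")
        line_a, line_b = lines

        # 4. CL vs CL DE ---------------------------------------------------
        stage("de_cell_lines")
        cl_a = cm.library_ids(cell_line=line_a, compartment="CL")
        cl_b = cm.library_ids(cell_line=line_b, compartment="CL")
        det_cl = detection.detected_set(f"{line_a}-CL") | detection.detected_set(f"{line_b}-CL")
        de_cl = run_de_contrast(cm, cl_a, cl_b, features=sorted(det_cl),
                                log2fc_cut=config.log2fc, p_cut=config.p,
                                fdr_cut=config.fdr)
        _write_de(de_cl, out / "de_cell_lines.tsv")
        bundle["de_cl"] = de_cl

        # 5. EV vs CL enrichment ------------------------------------------
        stage("ev_enrichment")
        ev_labels, ev_de = {}, {}
        for line in lines:
            cl = cm.library_ids(cell_line=line, compartment="CL")
            calls = {}
            for comp in ("sMV", "Exo"):
                ev = cm.library_ids(cell_line=line, compartment=comp)
                universe = (detection.detected_set(f"{line}-CL")
                            | detection.detected_set(f"{line}-{comp}"))
                de = run_de_contrast(cm, cl, ev, features=sorted(universe),
                                     log2fc_cut=config.log2fc, p_cut=config.p,
                                     fdr_cut=config.fdr)
                ev_de[f"{line}-{comp}"] = de
                _write_de(de, out / f"de_{line}-{comp}_vs_CL.tsv")
                calls[comp] = de["call"]
            universe = sorted(set(calls["sMV"].index) | set(calls["Exo"].index))
            smv = calls["sMV"].reindex(universe, fill_value="ns")
            exo = calls["Exo"].reindex(universe, fill_value="ns")
            ev_labels[line] = ev_enrichment_call(smv, exo)
        bundle["ev_labels"], bundle["ev_de"] = ev_labels, ev_de

        # 6. distribution report ------------------------------------------
        stage("distribution")
        cl_sets = {f"{line}-CL": detection.detected_set(f"{line}-CL") for line in lines}
        ev_sets = {f"{line}-{comp}": detection.detected_set(f"{line}-{comp}")
                   for line in lines for comp in ("sMV", "Exo")}
        reports = {
            "cell_lysates": venn_partition(cl_sets),
            "cross_cellline": cross_cellline_overlap(ev_sets),
        }
        for line in lines:
            reports[f"{line}_EVs"] = venn_partition(
                {c: ev_sets[f"{line}-{c}"] for c in ("sMV", "Exo")})
        write_json({k: r.to_dict() for k, r in reports.items()},
                   out / "distribution.json")
        bundle["distribution"] = reports

        # 7. cell-silent screen -------------------------------------------
        stage("cell_silent")
        silent = {}
        for line in lines:
            silent[line] = cell_silent_ev_screen(
                detection.detected_set(f"{line}-CL"), ev_labels[line])
        write_json({line: {k: sorted(v) for k, v in parts.items()}
                    for line, parts in silent.items()}, out / "cell_silent.json")
        bundle["cell_silent"] = silent

        # 7. signature ----------------------------------------------------
        stage("signature")
        # enrichment labels merged across cell lines: a feature is EV-
        # enriched when either line's EV-vs-CL analysis called it up
        universe = sorted(set(ev_labels[line_a].index) | set(ev_labels[line_b].index))
        merged_ev = pd.Series("none", index=pd.Index(universe, name="feature"))
        for line in lines:
            lab = ev_labels[line]
            enr = lab[lab != "none"]
            merged_ev.loc[enr.index] = enr.values
        features = select_features(
            config.signature_selection,
            detected=detection.detected_set(f"{line_a}-CL"),
            de_calls=de_cl["call"],
            ev_labels=merged_ev,
        )
        if len(features) < 3:
            # a null dataset can legitimately have (almost) no dysregulated
            # or EV-enriched features, and Pearson correlation needs at
            # least 3; fall back to the detected set so the downstream
            # stages still exercise their contracts
            logger.warning("signature selection %r has %d feature(s); "
                           "falling back to all_detected",
                           config.signature_selection, len(features))
            features = select_features(
                "all_detected", detected=detection.detected_set(f"{line_a}-CL"))
        sig_column = f"{line_a}-CL"
        signature = build_signature(mean_expr, sig_column, features)
        signature.to_csv(out / "signature.tsv", sep="\t",
                         index_label="feature", float_format="%.6g")
        bundle["signature"] = signature

        # 8. classification ------------------------------------------------
        stage("classify")
        if config.panel_path:
            panel = read_panel(config.panel_path)
        else:
            pconf = config.panel
            if pconf.seed != config.seed:
                pconf = type(pconf)(n_normals=pconf.n_normals,
                                    n_per_stage=pconf.n_per_stage,
                                    signature_weight=pconf.signature_weight,
                                    noise_sd=pconf.noise_sd, seed=config.seed)
            baseline = _panel_baseline(signature, config.seed)
            panel = generate_tumour_panel(pconf, signature, baseline)
            write_panel(panel, out / "panel.tsv")
        report = predict_samples(panel, signature, rule=config.classifier_rule,
                                 log_transform=config.log_transform)
        metrics = evaluate_classifier(report.samples["predicted"], panel.labels)
        write_json({"threshold": report.threshold, "rule": report.rule,
                    "metrics": metrics}, out / "classification.json")
        report.samples.to_csv(out / "classification.tsv", sep="\t",
                              index_label="sample", float_format="%.6g")
        bundle["classification"] = (report, metrics)

        # 9. motif scan ---------------------------------------------------
        stage("motif")
        if config.fasta_path:
            seqs = read_fasta(config.fasta_path)
        else:
            seqs = generate_precursor_set(
                n=334, length=config.precursor_length, motif=config.motifs[0],
                planted_fraction=config.precursor_planted_fraction,
                seed=config.seed)
            write_fasta(seqs, out / "precursors.fa")
        motif_reports = {}
        for m in config.motifs:
            rep = scan_motif(seqs, m)
            motif_reports[m] = {"n_sequences": rep.n_sequences,
                                "n_with_motif": rep.n_with_motif,
                                "fraction_pct": rep.fraction_pct,
                                "n_occurrences": rep.n_occurrences}
        write_json(motif_reports, out / "motifs.json")
        bundle["motifs"] = motif_reports
    except Exception:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        logger.exception("pipeline aborted at stage %r", failed)
        raise

    write_json(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


def asdict_sim(sim) -> dict:
    d = asdict(sim)
    d["compartments"] = tuple(tuple(x) for x in d["compartments"])
    return d


def _panel_baseline(signature: pd.Series, seed: int) -> pd.Series:
    """Normal-tissue-like baseline: independent heavy-tailed profile."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBA5E)))
    return pd.Series(10.0 ** rng.normal(2.0, 1.0, size=len(signature)),
                     index=signature.index)
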