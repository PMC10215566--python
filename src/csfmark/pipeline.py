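"""End-to-end orchestration of the discovery -> validation workflow.

``run_pipeline`` chains the stages on synthetic data with known ground
truth: simulate a TMT discovery study, normalize and merge the batches, run
the differential statistics, select candidates by the two-tier q-value rule
(tier 1: q < 0.05; tier 2: q < 0.1; PRM panel = tier 2 that is detectable),
simulate and quantify the PRM validation cohort, and evaluate the candidate
biomarkers. Every stage writes its table under the run directory and
contributes a block to ``summary.json``.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffstats, evaluate, prm, simulate, tmt
from .config import PrmSimSpec, RunConfig, SimulationConfig
from .fixtures import load_paper_fixtures

logger = logging.getLogger(__name__)

_AMINO_ACIDS = list("ACDEFGHILMNPQSTVWY")


def default_effect_table() -> dict[str, float]:
    """True effect sizes patterned on the discovery differential table:
    the packaged 53 proteins with their reported log2 fold changes."""
    table2 = load_paper_fixtures().table2
    return dict(zip(table2["gene_symbol"], table2["log2fc"]))


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _log_stage(stage: str, outputs: list[Path]) -> None:
    hashes = ", ".join(f"{p.name}={_file_hash(p)}" for p in outputs)
    logger.info("stage %s done: %s", stage, hashes)


def _synthetic_panel(
    proteins: list[str], rng: np.random.Generator, max_peptides: int = 2
) -> list[tuple[str, str, int]]:
    """1-2 synthetic tryptic peptides per protein (sequence, protein, ladder)."""
    panel = []
    for prot in proteins:
        for _ in range(int(rng.integers(1, max_peptides + 1))):
            length = int(rng.integers(7, 16))
            seq = "".join(rng.choice(_AMINO_ACIDS, length - 1)) + str(
                rng.choice(["K", "R"])
            )
            ladder = int(rng.integers(3, min(7, length - 1)))
            panel.append((seq, prot, ladder))
    return panel


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic study; returns the summary dict."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    try:
        # ---- stage 1: simulate the discovery study -------------------
        effects = dict(config.effect_table) or default_effect_table()
        sim_config = SimulationConfig(
            n_proteins=config.n_proteins,
            sigma_log2=config.sigma_log2,
            batch_effect_sd=config.batch_effect_sd,
            effect_table=effects,
            seed=config.seed,
        )
        batches, sheet, truth = simulate.simulate_discovery_study(sim_config)
        sheet_path = out / "sample_sheet.tsv"
        sheet.to_csv(sheet_path, sep="\t", index=False)
        batch_paths = []
        for b in batches:
            p = out / f"intensities_{b.batch_id}.tsv"
            b.data.to_csv(p, sep="\t", index_label="protein_id")
            batch_paths.append(p)
        summary["simulate"] = {
            "n_proteins": sim_config.n_proteins,
            "n_batches": len(batches),
            "n_discovery_samples": int(
                (sheet["cohort_role"] == "discovery+validation").sum()
            ),
            "n_effect_proteins": len(effects),
        }
        _log_stage("simulate", [sheet_path, *batch_paths])

        # ---- stage 2: TMT normalization ------------------------------
        normalized = [tmt.normalize_to_master_pool(b) for b in batches]
        merged, overlap = tmt.merge_batches(
            normalized,
            mode=config.merge_mode,
            impute=True,
            impute_scope=config.impute_scope,
        )
        merged = tmt.median_normalize(merged)
        matrix = tmt.log2_zscore(merged, axis=config.zscore_axis)
        matrix_path = out / "abundance_matrix.tsv"
        tmt.write_matrix_tsv(matrix, matrix_path)
        (out / "batch_overlap.json").write_text(json.dumps(overlap, indent=2))
        summary["tmt_quant"] = {
            "ledger": list(matrix.ledger),
            "overlap_counts": overlap,
        }
        _log_stage("tmt_quant", [matrix_path])

        # ---- stage 3: differential statistics ------------------------
        disc = sheet[sheet["cohort_role"] == "discovery+validation"]
        labels = pd.Series(
            disc["group"].to_numpy(), index=disc["subject_id"].to_numpy()
        )
        labels = labels[labels.index.isin(matrix.samples)]
        table = diffstats.differential_table(matrix, labels)
        table["q_value"] = diffstats.sam_qvalues(
            matrix, labels,
            n_permutations=config.n_permutations,
            seed=config.seed + 1,
            s0=config.sam_s0,
        )
        _, normal_fraction = diffstats.normality_screen(matrix, labels)
        n_real, n_ceil = diffstats.power_sample_size(
            diffstats.PowerSpec(delta=np.log2(1.5), sigma=config.sigma_log2)
        )
        table_path = out / "differential_table.tsv"
        table.to_csv(table_path, sep="\t")
        volcano = pd.DataFrame(
            {
                "log2fc": table["log2fc"],
                "neg_log10_p": -np.log10(table["p_value"].clip(lower=1e-300)),
                "significant": table["q_value"] < config.q_cutoff_tier1,
            }
        )
        volcano.to_csv(out / "volcano.tsv", sep="\t")
        summary["differential_stats"] = {
            "n_tested": len(table),
            "normal_fraction": normal_fraction,
            "power_sample_size": {"n": n_real, "ceil": n_ceil},
        }
        _log_stage("differential_stats", [table_path])

        # ---- stage 4: candidate selection ----------------------------
        tier1 = table.index[table["q_value"] < config.q_cutoff_tier1]
        tier2 = table.index[table["q_value"] < config.q_cutoff_tier2]
        detectable = truth.baseline_log2[
            truth.baseline_log2 >= config.detectability_min_log2
        ].index
        panel_proteins = [p for p in tier2 if p in set(detectable)]
        truth_fc = pd.Series(truth.protein_log2fc)
        recovered = [p for p in tier1 if truth_fc.get(p, 0.0) != 0.0]
        summary["candidate_selection"] = {
            "tier1_q_lt_%.2f" % config.q_cutoff_tier1: len(tier1),
            "tier2_q_lt_%.2f" % config.q_cutoff_tier2: len(tier2),
            "panel_proteins": len(panel_proteins),
            "tier1_true_positives": len(recovered),
        }

        if not panel_proteins:
            summary["prm_quant"] = {"note": "no candidates selected; PRM skipped"}
            summary["biomarker_eval"] = {"note": "no candidates selected"}
            _write_summary(out, summary)
            return summary

        # ---- stage 5: PRM validation ---------------------------------
        rng = np.random.default_rng(config.seed + 2)
        panel = _synthetic_panel(panel_proteins, rng)
        panel_df = pd.DataFrame(
            [(seq, prot) for seq, prot, _ in panel],
            columns=["peptide", "gene_symbol"],
        )
        truth = simulate.assign_peptide_concentrations(
            truth, panel_df, sheet,
            sigma_log2=config.validation_biological_sd,
            seed=config.seed + 3,
        )
        spec = PrmSimSpec(
            panel=panel, noise_cv=config.prm_noise_cv, seed=config.seed + 4
        )
        traces = simulate.simulate_prm_cohort(spec, sheet, truth)
        grouped: dict[tuple, list] = {}
        for t in traces:
            grouped.setdefault((t.peptide, t.sample_id, t.replicate), []).append(t)
        quant_rows = []
        by_pepsample: dict[tuple, list] = {}
        for (pep, sid, rep), tr in grouped.items():
            res = prm.quantify_peptide(
                tr, spike=float(truth.peptide_spikes[pep]), ion_rule=config.ion_rule
            )
            by_pepsample.setdefault((pep, sid), []).append(res)
        for (pep, sid), results in by_pepsample.items():
            mean_conc, cv = prm.summarize_replicates(results)
            quant_rows.append((pep, sid, mean_conc, cv))
        quant = pd.DataFrame(
            quant_rows,
            columns=["peptide", "sample_id", "concentration_pmol_per_ml", "cv_pct"],
        )
        quant_path = out / "prm_quant.tsv"
        quant.to_csv(quant_path, sep="\t", index=False)

        # response curves on the same panel
        series_spec = PrmSimSpec(
            panel=panel, noise_cv=config.prm_noise_cv,
            noise_floor=10.0, saturation_ceiling=5e6,
            seed=config.seed + 5,
        )
        series_traces, series_truth = simulate.simulate_response_series(series_spec)
        curve_rows = []
        by_pep_level: dict[tuple, list] = {}
        for t in series_traces:
            by_pep_level.setdefault((t.peptide, t.spike_fmol), []).append(t)
        responses: dict[str, dict[float, float]] = {}
        for (pep, level), tr in by_pep_level.items():
            area = float(
                np.mean(
                    [
                        sum(
                            prm.integrate_transition_peak(x)
                            for x in tr
                            if x.replicate == r
                        )
                        for r in range(1, series_spec.replicates + 1)
                    ]
                )
            )
            responses.setdefault(pep, {})[level] = area
        for pep, level_map in responses.items():
            levels = np.array(sorted(level_map))
            vals = np.array([level_map[l] for l in levels])
            fit = prm.fit_response_curve(
                pep, levels, vals,
                slope_band=config.linear_slope_band,
                min_r2=config.linear_min_r2,
            )
            curve_rows.append(
                (pep, fit.linear_low, fit.linear_high, fit.slope, fit.r_squared)
            )
        curves = pd.DataFrame(
            curve_rows,
            columns=["peptide", "linear_low_fmol", "linear_high_fmol", "slope", "r2"],
        )
        curves.to_csv(out / "response_curves.tsv", sep="\t", index=False)

        validation = sheet[sheet["cohort_role"].str.contains("validation")]
        vlabels = pd.Series(
            validation["group"].to_numpy(), index=validation["subject_id"].to_numpy()
        )
        conc_wide = quant.pivot(
            index="sample_id", columns="peptide", values="concentration_pmol_per_ml"
        ).loc[vlabels.index]
        test_rows = []
        for pep in conc_wide.columns:
            res = prm.validation_group_test(conc_wide[pep], vlabels)
            test_rows.append(
                (pep, res["p_value"], res["direction"], res["stars"])
            )
        tests = pd.DataFrame(
            test_rows, columns=["peptide", "p_value", "direction", "stars"]
        ).sort_values("p_value")
        tests.to_csv(out / "validation_tests.tsv", sep="\t", index=False)
        significant = tests[tests["p_value"] < config.p_cutoff_validation]
        summary["prm_quant"] = {
            "panel_peptides": len(panel),
            "median_cv_pct": float(quant["cv_pct"].median()),
            "peptides_with_linear_range": int(curves["linear_low_fmol"].notna().sum()),
            "significant_peptides": len(significant),
            "significant_up": int((significant["direction"] == "up").sum()),
            "significant_down": int((significant["direction"] == "down").sum()),
        }
        _log_stage("prm_quant", [quant_path])

        # ---- stage 6: biomarker evaluation ---------------------------
        pep_protein = dict(zip(panel_df["peptide"], panel_df["gene_symbol"]))
        X = np.log2(conc_wide.to_numpy(dtype=float))
        labels_arr = vlabels.to_numpy()
        roc_rows = []
        for pep in significant["peptide"]:
            boot = evaluate.bootstrap_auc(
                conc_wide[pep].to_numpy(dtype=float), labels_arr,
                n_boot=config.n_bootstrap, seed=config.seed + 6,
            )
            roc_rows.append((pep, boot.auc, boot.ci_low, boot.ci_high))
        roc_table = pd.DataFrame(
            roc_rows, columns=["peptide", "auc", "ci_low", "ci_high"]
        ).sort_values("auc", ascending=False)
        roc_table.to_csv(out / "univariate_roc.tsv", sep="\t", index=False)

        val_fc = np.log2(
            conc_wide[labels_arr == "ALS"].mean()
            / conc_wide[labels_arr == "HC"].mean()
        )
        val_fc_protein = val_fc.groupby(val_fc.index.map(pep_protein)).mean()
        disc_fc = table["log2fc"]
        try:
            corr, pairs = evaluate.correlate_discovery_validation(
                disc_fc, val_fc_protein
            )
            pairs.to_csv(out / "discovery_validation_pairs.tsv", sep="\t")
        except ValueError:
            corr = float("nan")

        sizes = [k for k in config.panel_sizes if k <= X.shape[1]] or [X.shape[1]]
        panel_eval = evaluate.mccv_panel_evaluation(
            X, labels_arr,
            panel_sizes=sizes,
            n_repeats=config.mccv_repeats,
            seed=config.seed + 7,
            feature_names=list(conc_wide.columns),
        )
        panel_eval.importance.to_csv(out / "feature_importance.tsv", sep="\t")
        summary["biomarker_eval"] = {
            "best_univariate_auc": float(roc_table["auc"].max()) if len(roc_table) else None,
            "discovery_validation_r": corr,
            "panel_auc": {str(k): v for k, v in panel_eval.auc_mean.items()},
            "panel_accuracy": {str(k): v for k, v in panel_eval.accuracy.items()},
        }
        _log_stage("biomarker_eval", [out / "univariate_roc.tsv"])
    except Exception as exc:
        _write_summary(out, summary)
        raise RuntimeError(
            f"pipeline failed after stage(s) {list(summary)}: {exc}"
        ) from exc

    _write_summary(out, summary)
    return summary


def _write_summary(out: Path, summary: dict) -> None:
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
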