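"""End-to-end experiment: simulate → profile → group-fit → train → infer →
evaluate → laterality.

The experiment emulates, at desk scale, a six-way comparison of parcellation
approaches: three group-average atlases (one matching the test cohort's
"site", two from other "sites" with different group topographies) and three
MS-HBM models trained on those sites.  Test subjects come from the first
site; matched-site individual models should win on leave-one-run-out
homogeneity and on stimulation inhomogeneity, and the matched-site
individual parcellations drive the laterality analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as co
from . import evaluation as ev
from . import io as eio
from . import laterality as lat
from . import mshbm, profiles, vmf
from .graph import build_cortical_graph

log = logging.getLogger("epiparc")

SITES = ("siteA", "siteB", "siteC")   # siteA matches the test cohort


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:12]


def _profiles_for(runs_by_subject, mask, top_fraction):
    return {s: [profiles.compute_profile(r, mask, top_fraction) for r in rlist]
            for s, rlist in runs_by_subject.items()}


def _group_runs(runs: dict) -> dict:
    by_subject: dict[int, list] = {}
    for (s, t) in sorted(runs):
        by_subject.setdefault(s, []).append(runs[(s, t)])
    return by_subject


def run_pipeline(config: eio.ExperimentConfig) -> dict:
    """Execute the full experiment; returns the report dict and writes all
    artifacts under ``config.out_dir``. Bit-reproducible for a fixed
    (config, root_seed)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.json")
    ss = np.random.SeedSequence(config.root_seed)
    seeds = {name: child for name, child in zip(
        ("graph", "test_cohort", "siteA", "siteB", "siteC",
         "group_fit", "train", "stim"), ss.spawn(8))}

    report: dict = {"stages": [], "config_seed": config.root_seed}

    def stage(name, artifacts):
        log.info("stage %s done (%s)", name, ", ".join(artifacts))
        report["stages"].append({"stage": name, "artifacts": artifacts})

    try:
        # -- simulate ------------------------------------------------------
        graph = build_cortical_graph(config.n_per_hemisphere, config.topology)
        dominance = co.default_dominance_list(config.dominance_design)
        test_truth, test_runs = co.generate_cohort(
            graph, K=config.K, R=config.R, dominance=dominance,
            n_runs=config.n_test_runs, T=config.T, snr=config.snr,
            deviation_rate=config.deviation_rate,
            seed=seeds["test_cohort"].generate_state(1)[0] % (2**31))
        eio.write_cohort(test_truth, test_runs, out / "cohort_test")

        site_truths, site_runs = {}, {}
        for site in SITES:
            base = test_truth if site == "siteA" else None
            truth, runs = co.generate_cohort(
                graph, K=config.K, R=config.R,
                n_subjects=config.n_train_subjects,
                n_runs=config.n_train_runs, T=config.T, snr=config.snr,
                deviation_rate=config.deviation_rate,
                seed=seeds[site].generate_state(1)[0] % (2**31),
                group_labels_from=base)
            site_truths[site], site_runs[site] = truth, runs
        stage("simulate", ["cohort_test"])

        # -- profile -------------------------------------------------------
        test_prof = _profiles_for(_group_runs(test_runs), graph.cortex_mask,
                                  config.top_fraction)
        site_prof = {site: _profiles_for(_group_runs(site_runs[site]),
                                         graph.cortex_mask, config.top_fraction)
                     for site in SITES}
        stage("profile", [])

        # -- group fit + MS-HBM training per site --------------------------
        atlases, models = {}, {}
        fit_children = seeds["group_fit"].spawn(len(SITES))
        train_children = seeds["train"].spawn(len(SITES))
        for site, fs, ts in zip(SITES, fit_children, train_children):
            plist = site_prof[site]
            rows = np.concatenate([p.matrix for ps in plist.values() for p in ps])
            vidx = np.concatenate([np.arange(graph.n_vertices)
                                   for ps in plist.values() for p in ps])
            keep = np.linalg.norm(rows, axis=1) > 0
            mix, parc = vmf.fit_vmf_mixture(
                rows[keep], config.K, vertex_index=vidx[keep],
                n_vertices=graph.n_vertices, mask=graph.cortex_mask,
                n_init=config.n_init, max_iter=config.vmf_max_iter,
                seed=int(fs.generate_state(1)[0] % (2**31)), source=site)
            # align mixture components to the planted ROI structure so that
            # network identities (incl. language ids) are comparable across sites
            perm = mshbm.match_networks(
                parc.labels, site_truths[site].group_labels, config.K)
            parc.labels = mshbm.relabel(parc.labels, perm)
            order = np.argsort(perm)
            mix.mu, mix.kappa, mix.weights = mix.mu[order], mix.kappa[order], mix.weights[order]
            atlases[site] = parc
            models[site] = mshbm.train_mshbm(
                [plist[s] for s in sorted(plist)], graph, parc, mix,
                c=config.c, max_iter=config.train_max_iter,
                trained_on=site, seed=int(ts.generate_state(1)[0] % (2**31)))
            eio.write_parcellation(parc.labels, config.K,
                                   out / f"atlas_{site}_labels.txt",
                                   out / f"atlas_{site}_lut.txt")
            eio.write_model(models[site], out / f"mshbm_{site}.npz")
        stage("group-fit+train", [f"mshbm_{s}.npz" for s in SITES])

        # -- infer + evaluate: six-way LORO homogeneity ---------------------
        approaches = [f"atlas_{s}" for s in SITES] + [f"mshbm_{s}" for s in SITES]
        eval_subjects = sorted(_group_runs(test_runs))[:config.n_eval_subjects]

        def make_source(site, kind):
            if kind == "atlas":
                return lambda train_runs: atlases[site].labels
            def source(train_runs):
                profs = [profiles.compute_profile(r, graph.cortex_mask,
                                                  config.top_fraction)
                         for r in train_runs]
                return mshbm.infer_individual(models[site], profs, graph,
                                              max_iter=config.infer_max_iter).labels
            return source

        hom = np.zeros((len(eval_subjects), len(approaches)))
        runs_by_subject = _group_runs(test_runs)
        for si, s in enumerate(eval_subjects):
            for ai, name in enumerate(approaches):
                kind, site = name.split("_")
                value, _ = ev.loro_evaluate(
                    runs_by_subject[s], make_source(site, kind),
                    lambda labels, run: ev.resting_homogeneity(
                        labels, run, config.K).value)
                hom[si, ai] = value
        hom_stats = ev.compare_approaches(hom, approaches)
        pd.DataFrame(hom, index=eval_subjects, columns=approaches)\
            .to_csv(out / "homogeneity.csv")
        stage("evaluate-homogeneity", ["homogeneity.csv"])

        # -- stimulation arm -----------------------------------------------
        design = co.make_alternating_design(config.stim_blocks,
                                            config.frames_per_block,
                                            discard_frames=config.discard_frames)
        stim_children = seeds["stim"].spawn(len(eval_subjects))
        inho = np.zeros((len(eval_subjects), len(approaches)))
        subj_parcs = {}   # matched-site individual parcellations (all runs)
        for si, (s, child) in enumerate(zip(eval_subjects, stim_children)):
            run, _ = co.simulate_stim_run(
                test_truth, s, design, config.stim_networks,
                effect=config.stim_effect, snr=config.snr,
                seed=int(child.generate_state(1)[0] % (2**31)))
            zmap = ev.stim_glm(run, design)
            for ai, name in enumerate(approaches):
                kind, site = name.split("_")
                labels = make_source(site, kind)(runs_by_subject[s])
                if name == "mshbm_siteA":
                    subj_parcs[s] = labels
                inho[si, ai] = ev.task_inhomogeneity(labels, zmap, config.K).value
        inho_stats = ev.compare_approaches(inho, approaches)
        pd.DataFrame(inho, index=eval_subjects, columns=approaches)\
            .to_csv(out / "inhomogeneity.csv")
        stage("evaluate-stimulation", ["inhomogeneity.csv"])

        # -- laterality ----------------------------------------------------
        all_subjects = sorted(runs_by_subject)
        records = []
        for s in all_subjects:
            if s in subj_parcs:
                labels = subj_parcs[s]
            else:
                labels = make_source("siteA", "mshbm")(runs_by_subject[s])
                subj_parcs[s] = labels
            records.append(lat.compute_li(labels, graph, test_truth.language_ids,
                                          subject_id=s,
                                          dominance=test_truth.dominance[s]))
        anova = lat.anova_li(records)
        rocs = {g: lat.roc_auc(records, g) for g in ("left", "bilateral", "right")}
        dice = lat.inter_subject_dice([subj_parcs[s] for s in all_subjects],
                                      config.K)
        pd.DataFrame([{"subject_id": r.subject_id, "lh": r.lh_count,
                       "rh": r.rh_count, "li": r.li, "dominance": r.dominance}
                      for r in records]).to_csv(out / "laterality.csv", index=False)
        stage("laterality", ["laterality.csv"])

        # -- report --------------------------------------------------------
        def stats_block(st: ev.PairwiseStats):
            return {"approaches": st.approaches, "dof": st.dof,
                    "n_pairs": int(np.sum(~np.tril(np.ones_like(st.p, bool)))),
                    "t": np.round(st.t, 10).tolist(),
                    "p": np.round(st.p, 10).tolist(),
                    "q": np.round(st.q, 10).tolist(),
                    "significant": st.significant.tolist()}

        report.update({
            "homogeneity": {
                "mean_by_approach": dict(zip(approaches,
                                             np.round(hom.mean(axis=0), 10))),
                "stats": stats_block(hom_stats)},
            "inhomogeneity": {
                "mean_by_approach": dict(zip(approaches,
                                             np.round(inho.mean(axis=0), 10))),
                "stats": stats_block(inho_stats)},
            "dice": {"per_network_mean":
                     np.round(dice.per_network_mean, 10).tolist()},
            "laterality": {
                "group_means": dict(zip(anova.groups,
                                        np.round(anova.group_means, 10))),
                "group_sds": dict(zip(anova.groups,
                                      np.round(anova.group_sds, 10))),
                "anova_F": round(anova.F, 10), "anova_p": round(anova.p, 10),
                "auc": {g: round(rocs[g].auc, 10) for g in rocs}},
            "artifact_hashes": {
                "homogeneity": _hash_array(hom),
                "inhomogeneity": _hash_array(inho),
            },
        })
        with open(out / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        return report
    except Exception as e:
        raise RuntimeError(
            f"pipeline halted in stage "
            f"{report['stages'][-1]['stage'] if report['stages'] else 'simulate'}"
            f" (artifacts under {out}): {e}") from e
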