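"""End-to-end orchestration: simulate -> score -> associate -> mediate -> twin.

`run_all` reproduces the full analytic chain on a synthetic cohort and
writes table-style TSVs (descriptives, paternal-age associations,
mediation), a variance-function table for the moderation model, a single
deterministic JSON results bundle, and a run manifest.  All randomness
derives from one root seed via fixed per-stage offsets, so a rerun with
the same config and seed is byte-identical (manifest timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, gi, synth, twin
from .mediate import DEFAULT_COVARIATES as DEFAULT_MED_COVARIATES
from .mediate import mediate_by_sex

log = logging.getLogger("geekdex")

PATERNAL_BANDS = [(-np.inf, 25, "<25"), (25, 35, "25-34"), (35, 45, "35-44"), (45, 51, "45-50"), (51, np.inf, ">50")]
MATERNAL_BANDS = [(-np.inf, 21, "<20"), (21, 31, "21-30"), (31, 41, "31-40"), (41, np.inf, ">40")]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    started: str
    finished: str
    row_counts: dict
    outputs: list

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _stage_seed(seed: int, stage: int) -> int:
    # documented derivation: independent stream per stage, < 2**31
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def describe_cohort(cohort: pd.DataFrame, gi_col: str = "gi_default") -> pd.DataFrame:
    """Mean GI with standard error and N per stratum (whole sample, sex,
    zygosity, parental-age bands, autism status)."""
    rows = []

    def add(group, stratum, sub):
        v = sub[gi_col].astype(float)
        n = len(sub)
        rows.append(
            {
                "grouping": group,
                "stratum": stratum,
                "mean_gi": float(v.mean()) if n else float("nan"),
                "se": float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                "n": n,
            }
        )

    add("all", "all", cohort)
    for sex, label in (("F", "Females"), ("M", "Males")):
        add("sex", label, cohort[cohort["sex"] == sex])
    for z in ("MZ", "DZ"):
        add("zygosity", z, cohort[cohort["zygosity"] == z])
    for col, bands, group in (("paternal_age", PATERNAL_BANDS, "paternal_age"), ("maternal_age", MATERNAL_BANDS, "maternal_age")):
        for lo, hi, label in bands:
            add(group, label, cohort[(cohort[col] >= lo) & (cohort[col] < hi)])
    add("autism", "Affected", cohort[cohort["autism_flag"].astype(bool)])
    add("autism", "Non-affected", cohort[~cohort["autism_flag"].astype(bool)])
    return pd.DataFrame(rows)


def _fit_robust(outcome: str, terms: list, sub: pd.DataFrame):
    """Fit, dropping constant or collinear covariates at small n rather
    than aborting the whole pipeline (the first term is always kept)."""
    keep = [terms[0]] + [t for t in terms[1:] if sub[t].nunique() > 1]
    while True:
        try:
            return assoc.fit_lmm(outcome, keep, sub)
        except ValueError as exc:
            dropped = [t for t in keep[1:] if t in str(exc)]
            if not dropped:
                dropped = keep[-1:]
            if len(keep) == 1:
                raise
            keep = [t for t in keep if t not in dropped]
            log.warning("dropping collinear covariate(s) %s from %s model", dropped, outcome)


def _table2(cohort: pd.DataFrame) -> pd.DataFrame:
    """Crude and adjusted paternal-age effect on GI, pooled and by sex."""
    rows = []
    for sex_label, sub in (("M+F", cohort), ("M", cohort[cohort["sex"] == "M"]), ("F", cohort[cohort["sex"] == "F"])):
        covs = [c for c in assoc.ADJUSTED_COVARIATES if not (sex_label != "M+F" and c == "sex")]
        crude = assoc.fit_lmm("gi_default", ["paternal_age"], sub)
        adj = _fit_robust("gi_default", ["paternal_age", *covs], sub)
        rows.append(
            {
                "sex": sex_label,
                "beta_crude": crude.beta("paternal_age"),
                "se_crude": crude.se("paternal_age"),
                "p_crude": crude.p("paternal_age"),
                "n_crude": crude.n_children,
                "beta_adjusted": adj.beta("paternal_age"),
                "se_adjusted": adj.se("paternal_age"),
                "p_adjusted": adj.p("paternal_age"),
                "n_adjusted": adj.n_children,
            }
        )
    return pd.DataFrame(rows)


def _twin_stage(cohort: pd.DataFrame, seed: int):
    pairs = twin.pairs_from_cohort(cohort, "gi_default", moderator="paternal_age")
    corr = twin.twin_correlations(pairs)
    ae = twin.fit_ae(pairs, seed=seed)
    ade = twin.fit_ade(pairs, seed=seed)
    resid = twin.regress_out_moderator(pairs)
    gxe = twin.fit_gxe(resid, seed=seed)
    summary = {
        "correlations": {
            "r_mz": corr.r_mz,
            "r_mz_ci": list(corr.r_mz_ci),
            "r_dz": corr.r_dz,
            "r_dz_ci": list(corr.r_dz_ci),
            "n_mz_pairs": corr.n_mz_pairs,
            "n_dz_pairs": corr.n_dz_pairs,
        },
        "ae": {"a": ae.a, "e": ae.e, "a2_share": ae.std_components["a2"], "e2_share": ae.std_components["e2"], "loglik": ae.loglik},
        "ade": {"a": ade.a, "d": ade.d, "e": ade.e, "std_components": ade.std_components, "loglik": ade.loglik},
        "gxe": {"a": gxe.a, "e": gxe.e, "beta_a": gxe.beta_a, "beta_e": gxe.beta_e, "loglik": gxe.loglik, "cis": {k: list(v) for k, v in gxe.cis.items()}},
    }
    return summary, twin.moderated_variance_table(gxe)


def run_all(config, out_dir, seed: int = 0, n_sims: int = 1000) -> RunManifest:
    """Execute the full pipeline; ``config`` is a SimConfig, a preset name,
    or a path to a YAML preset file (first preset used)."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if isinstance(config, synth.SimConfig):
        cfg = config
    elif isinstance(config, str) and not Path(config).exists():
        cfg = synth.load_preset(config)
    else:
        import yaml

        with open(config, encoding="utf-8") as fh:
            presets = yaml.safe_load(fh)
        cfg = synth.load_preset(next(iter(presets)), path=config)
    cfg = dataclasses.replace(cfg, seed=_stage_seed(seed, 0))
    cfg_hash = hashlib.sha256(json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=list).encode()).hexdigest()
    log.info("run_all: seed=%d config_hash=%s", seed, cfg_hash[:12])

    manifest_counts = {}
    outputs = []
    results = {"seed": seed, "config_hash": cfg_hash}

    def write_tsv(df: pd.DataFrame, name: str):
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        outputs.append(str(path))
        manifest_counts[name] = len(df)

    stage = "simulate"
    try:
        cohort = synth.simulate_cohort_frame(cfg)
        if cfg.n_families < 50:
            log.warning("small cohort (%d families): estimates will be unstable", cfg.n_families)
        stage = "score"
        cohort = gi.score_cohort(cohort)
        path = out / "cohort.csv"
        synth.write_cohort(cohort, path)
        outputs.append(str(path))
        manifest_counts["cohort.csv"] = len(cohort)

        stage = "describe"
        write_tsv(describe_cohort(cohort), "table1_descriptives.tsv")

        stage = "assoc"
        t2 = _table2(cohort)
        write_tsv(t2, "table2_paternal_age.tsv")
        sens_rows = []
        for label, kw in (("paternal_age<=50", {"max_paternal_age": 50}), ("no_autism", {"exclude_autism": True})):
            sub = assoc.sensitivity_filters(cohort, **kw)
            fit = assoc.fit_lmm("gi_default", ["paternal_age", *assoc.ADJUSTED_COVARIATES], sub)
            sens_rows.append({"subset": label, "beta": fit.beta("paternal_age"), "se": fit.se("paternal_age"), "p": fit.p("paternal_age"), "n": fit.n_children})
        write_tsv(pd.DataFrame(sens_rows), "table2_sensitivity.tsv")
        delta, dof, p_quad = assoc.lrt_quadratic(cohort)
        write_tsv(assoc.subscale_vs_gi_comparison(cohort).reset_index(), "subscale_comparison.tsv")
        write_tsv(assoc.geek_cluster_groups(cohort).reset_index(), "cluster_groups.tsv")
        results["assoc"] = {
            "table2": t2.to_dict(orient="records"),
            "sensitivity": sens_rows,
            "lrt_quadratic": {"delta_loglik": delta, "df": dof, "p": p_quad},
        }

        stage = "mediate"
        med_covs = list(DEFAULT_MED_COVARIATES)
        while True:
            try:
                med = mediate_by_sex(cohort, covariates=med_covs, n_sims=n_sims, seed=_stage_seed(seed, 2))
                break
            except ValueError as exc:
                dropped = [c for c in med_covs if c in str(exc)]
                if not dropped:
                    raise
                med_covs = [c for c in med_covs if c not in dropped]
                log.warning("dropping collinear mediation covariate(s) %s", dropped)
        t3 = pd.DataFrame(
            [
                {
                    "sex": {"pooled": "M+F"}.get(k, k),
                    "acme": r.acme.estimate,
                    "acme_low": r.acme.ci_low,
                    "acme_high": r.acme.ci_high,
                    "acme_p": r.acme.p,
                    "direct": r.direct.estimate,
                    "direct_low": r.direct.ci_low,
                    "direct_high": r.direct.ci_high,
                    "direct_p": r.direct.p,
                    "total": r.total.estimate,
                    "total_low": r.total.ci_low,
                    "total_high": r.total.ci_high,
                    "total_p": r.total.p,
                }
                for k, r in med.items()
            ]
        )
        write_tsv(t3, "table3_mediation.tsv")
        results["mediation"] = {k: r.as_dict() for k, r in med.items()}

        stage = "twin"
        twin_results, var_table = _twin_stage(cohort, seed=_stage_seed(seed, 3))
        write_tsv(var_table, "fig2_variance_function.tsv")
        results["twin"] = twin_results
    except Exception as exc:
        partial = RunManifest(cfg_hash, seed, _version(), started, time.strftime("%Y-%m-%dT%H:%M:%S"), manifest_counts, outputs)
        (out / "manifest.json").write_text(partial.to_json())
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle = out / "results.json"
    bundle.write_text(json.dumps(results, indent=2, sort_keys=True))
    outputs.append(str(bundle))
    manifest_counts["results.json"] = 1

    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=seed,
        package_version=_version(),
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        row_counts=manifest_counts,
        outputs=outputs,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _version() -> str:
    from . import __version__

    return __version__
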