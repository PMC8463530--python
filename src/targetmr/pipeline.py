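"""End-to-end orchestration: simulate -> instruments -> MR -> meta -> concordance.

One YAML config drives the whole run; every threshold, seed and per-stage
record count lands in a JSON run manifest together with SHA-256 checksums
of the written outputs, so two runs from one config are bit-identical and
every reported estimate is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from targetmr import __version__
from targetmr.concordance import (
    CLUSTER_FLOOR,
    build_evidence_matrix,
    cluster_matrix,
    write_matrix,
)
from targetmr.gwas_io import (
    CisWindow,
    SummaryTable,
    extract_cis_window,
    harmonize,
    read_summary_stats,
    write_exclusions,
    write_summary_stats,
)
from targetmr.instruments import apply_instrument_filters, greedy_clump, ld_from_reference
from targetmr.mr_core import (
    MRInput,
    MRResult,
    MVMRInput,
    gls_ivw,
    mvmr_gls,
    orient_canonical,
    prune_leverage_outliers,
)
from targetmr.synthetic_data import SimConfig, TrialSimConfig, gen_trialset, gen_two_sample_summary
from targetmr.trial_meta import between_compound_q, compound_meta, read_trials


class ConfigError(ValueError):
    """Raised before any computation when the config fails validation."""


DEFAULTS = {
    "maf_min": 0.01,
    "f_min": 15.0,
    "r2_max": 0.40,
    "palindrome_eaf_limit": 0.42,
    "prune": True,
    "leverage_mult": 3.0,
    "prune_alpha": 0.05,
    "overdispersion": False,
    "direction": "decrease",
    "meta_model": "fixed",
    "floor": CLUSTER_FLOOR,
    "transform": "sqrt_signed",
    "metric": "euclidean",
    "linkage": "complete",
}


def mr_analysis(
    exposure: SummaryTable,
    outcome: SummaryTable,
    reference: pd.DataFrame,
    window: CisWindow | None = None,
    maf_min: float = 0.01,
    f_min: float = 15.0,
    r2_max: float = 0.40,
    palindrome_eaf_limit: float = 0.42,
    prune: bool = True,
    leverage_mult: float = 3.0,
    prune_alpha: float = 0.05,
    overdispersion: bool = False,
    direction: str = "decrease",
) -> tuple[MRResult, dict]:
    """The univariable cis-MR chain on in-memory tables.

    Window -> harmonize -> MAF/F filters -> reference LD -> clump at r2_max
    -> optional leverage/outlier pruning -> GLS-IVW -> canonical
    orientation.  Returns the oriented result plus a provenance dict with
    per-stage counts and all exclusions.
    """
    if window is not None:
        exposure = extract_cis_window(exposure, window)
    pairs = harmonize(exposure, outcome, palindrome_eaf_limit=palindrome_eaf_limit)
    n_harmonized = len(pairs)
    pairs = apply_instrument_filters(pairs, maf_min=maf_min, f_min=f_min)
    n_filtered = len(pairs)
    if n_filtered == 0:
        raise ValueError("no variants survive the instrument filters")
    ld = ld_from_reference(reference[list(pairs.df["key"])])
    inst = greedy_clump(pairs, ld, r2_max=r2_max)
    n_clumped = len(inst)
    inp = MRInput.from_instrument_set(inst)
    pruned: list = []
    if prune and inp.m >= 3:
        inp, pruned = prune_leverage_outliers(
            inp, leverage_mult=leverage_mult, alpha=prune_alpha
        )
    res = gls_ivw(inp, overdispersion=overdispersion)
    res.excluded = pruned
    res = orient_canonical(res, {inp.exposure_name: direction})
    provenance = {
        "n_harmonized": n_harmonized,
        "n_filtered": n_filtered,
        "n_clumped": n_clumped,
        "n_pruned": len(pruned),
        "n_used": res.m_used,
        "exclusions": inst.pairs.exclusions,
        "pruned": pruned,
    }
    return res, provenance


def mvmr_analysis(
    exposures: dict[str, SummaryTable],
    outcome: SummaryTable,
    reference: pd.DataFrame,
    directions: dict[str, str],
    maf_min: float = 0.01,
    f_min: float = 15.0,
    r2_max: float = 0.40,
) -> MRResult:
    """Multivariable cis-MR: joint slopes for several candidate mediators.

    Instruments are harmonized to the first exposure, filtered on the
    maximum per-variant F across exposures (a variant only needs to
    instrument one mediator strongly), clumped, then fit jointly.
    """
    names = list(exposures)
    first = names[0]
    pairs_by_exp = {n: harmonize(exposures[n], outcome) for n in names}
    common = set(pairs_by_exp[first].df["key"])
    for n in names[1:]:
        common &= set(pairs_by_exp[n].df["key"])
    base = pairs_by_exp[first]
    base_df = base.df[base.df["key"].isin(common)].reset_index(drop=True)

    b_cols = {}
    for n in names:
        d = pairs_by_exp[n].df.set_index("key")
        b_cols[n] = d.loc[base_df["key"], ["b_x", "s_x"]].to_numpy()
    f_max = np.max(
        [(b_cols[n][:, 0] / b_cols[n][:, 1]) ** 2 for n in names], axis=0
    )
    eaf = base_df["eaf"].to_numpy()
    keep = (np.minimum(eaf, 1 - eaf) >= maf_min) & (f_max >= f_min)
    base_df = base_df[keep].reset_index(drop=True)
    if len(base_df) <= len(names):
        raise ValueError("too few instruments for multivariable MR after filtering")

    ld = ld_from_reference(reference[list(base_df["key"])])
    base_kept = dataclasses.replace(base, df=base_df)
    inst = greedy_clump(base_kept, ld, r2_max=r2_max)
    kept_keys = list(inst.pairs.df["key"])
    B_x = np.column_stack(
        [pairs_by_exp[n].df.set_index("key").loc[kept_keys, "b_x"].to_numpy() for n in names]
    )
    d0 = inst.pairs.df
    inp = MVMRInput(
        B_x=B_x,
        exposure_names=names,
        b_y=d0["b_y"].to_numpy(),
        s_y=d0["s_y"].to_numpy(),
        rho=inst.ld.r,
        variant_keys=kept_keys,
        outcome_name=outcome.trait_name,
    )
    res = mvmr_gls(inp)
    return orient_canonical(res, directions)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "seed" not in cfg:
        raise ConfigError("config requires an explicit seed")
    stages = cfg.get("stages", ["simulate", "mr", "meta", "concord"])
    known = {"simulate", "mr", "mvmr", "meta", "concord"}
    bad = [s for s in stages if s not in known]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    cfg["stages"] = stages
    merged = dict(DEFAULTS)
    merged.update(cfg.get("options", {}))
    unknown_opts = set(merged) - set(DEFAULTS)
    if unknown_opts:
        raise ConfigError(f"unknown options: {sorted(unknown_opts)}")
    cfg["options"] = merged
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured stages and write a results bundle + manifest.

    Stage outputs are flushed as each stage completes, so a later failure
    preserves earlier results; the manifest records the failed stage.
    Identical config (including seed) produces identical checksums.
    """
    cfg = load_config(config) if not isinstance(config, dict) else validate_config(dict(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opt = cfg["options"]
    seed = int(cfg["seed"])
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": _jsonable(cfg),
        "stages": {},
        "files": {},
        "failed_stage": None,
    }

    state: dict = {}
    try:
        for stage in cfg["stages"]:
            if stage == "simulate":
                _stage_simulate(cfg, seed, out, state, manifest)
            elif stage == "mr":
                _stage_mr(cfg, opt, out, state, manifest)
            elif stage == "mvmr":
                _stage_mvmr(cfg, opt, out, state, manifest)
            elif stage == "meta":
                _stage_meta(cfg, opt, out, state, manifest)
            elif stage == "concord":
                _stage_concord(opt, out, state, manifest)
    except Exception as err:
        manifest["failed_stage"] = {"stage": stage, "error": str(err)}
        _write_manifest(manifest, out)
        raise
    _write_manifest(manifest, out)
    return manifest


def _stage_simulate(cfg, seed, out, state, manifest):
    sim = cfg.get("simulate", {})
    gcfg = SimConfig(**{**sim.get("gwas", {}), "seed": seed})
    exposures, outcome, reference, truth = gen_two_sample_summary(gcfg)
    tcfg = TrialSimConfig(**{**sim.get("trials", {}), "seed": seed + 1})
    trials_df, trial_truth = gen_trialset(tcfg)
    state.update(
        exposures=exposures, outcome=outcome, reference=reference,
        truth=truth, trials_df=trials_df, trial_truth=trial_truth,
    )
    for name, tbl in exposures.items():
        _flush_table(tbl, out / f"sim_exposure_{name}.tsv", manifest)
    _flush_table(outcome, out / "sim_outcome.tsv", manifest)
    p = out / "sim_trials.csv"
    trials_df.to_csv(p, index=False)
    _register(p, manifest)
    manifest["stages"]["simulate"] = {
        "m": gcfg.m, "n_exposure": gcfg.n_exposure, "n_outcome": gcfg.n_outcome,
        "n_reference": gcfg.n_reference, "n_trial_rows": len(trials_df),
    }


def _stage_mr(cfg, opt, out, state, manifest):
    if "exposures" not in state:
        state.update(_load_inputs(cfg))
    rows = []
    results = {}
    for name, exp_tbl in state["exposures"].items():
        res, prov = mr_analysis(
            exp_tbl, state["outcome"], state["reference"],
            maf_min=opt["maf_min"], f_min=opt["f_min"], r2_max=opt["r2_max"],
            palindrome_eaf_limit=opt["palindrome_eaf_limit"],
            prune=opt["prune"], leverage_mult=opt["leverage_mult"],
            prune_alpha=opt["prune_alpha"], overdispersion=opt["overdispersion"],
            direction=opt["direction"],
        )
        results[name] = res
        theta, se, p = res.single()
        rows.append(
            dict(exposure=name, outcome=res.outcome_name, theta=theta, se=se,
                 p=p, Q=res.Q, df_Q=res.df_Q, m_used=res.m_used,
                 orientation=res.orientation)
        )
        manifest["stages"].setdefault("mr", {})[name] = {
            k: v for k, v in prov.items() if isinstance(v, int)
        }
        write_exclusions(prov["exclusions"], out / f"mr_exclusions_{name}.tsv")
        _register(out / f"mr_exclusions_{name}.tsv", manifest)
    state["mr_results"] = results
    p = out / "mr_results.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.10g")
    _register(p, manifest)


def _stage_mvmr(cfg, opt, out, state, manifest):
    if "exposures" not in state:
        state.update(_load_inputs(cfg))
    med_names = [n for n in state["exposures"] if n != "protein"]
    if len(med_names) < 2:
        raise ConfigError("mvmr stage needs at least two mediator exposures")
    directions = {n: opt["direction"] for n in med_names}
    res = mvmr_analysis(
        {n: state["exposures"][n] for n in med_names},
        state["outcome"], state["reference"], directions,
        maf_min=opt["maf_min"], f_min=opt["f_min"], r2_max=opt["r2_max"],
    )
    state["mvmr_result"] = res
    p = out / "mvmr_results.tsv"
    pd.DataFrame(
        dict(exposure=res.exposure_names, theta=res.theta, se=res.se, p=res.p)
    ).to_csv(p, sep="\t", index=False, float_format="%.10g")
    _register(p, manifest)
    manifest["stages"]["mvmr"] = {"m_used": res.m_used, "k": len(res.exposure_names)}


def _stage_meta(cfg, opt, out, state, manifest):
    if "trials_df" not in state:
        trials = read_trials(cfg["meta"]["trials"])
    else:
        trials = read_trials_frame(state["trials_df"])
    outcomes = sorted({t.outcome for t in trials})
    all_rows = []
    per_outcome = {}
    for oc in outcomes:
        pooled, excl = compound_meta(trials, oc, model=opt["meta_model"])
        per_outcome[oc] = pooled
        for c, m in pooled.items():
            all_rows.append(
                dict(outcome=oc, compound=c, effect=m.effect, se=m.se,
                     ci_low=m.ci_low, ci_high=m.ci_high, p=m.p,
                     Q_within=m.Q_within, df=m.df, tau2=m.tau2,
                     k=m.k_studies, model=m.model, scale=m.scale)
            )
        if len(pooled) >= 2:
            q, df, pq = between_compound_q(list(pooled.values()))
            manifest["stages"].setdefault("meta", {})[oc] = {
                "Q_between": q, "df": df, "p": pq, "n_excluded": len(excl),
            }
    state["meta_results"] = per_outcome
    p = out / "meta_results.tsv"
    pd.DataFrame(all_rows).to_csv(p, sep="\t", index=False, float_format="%.10g")
    _register(p, manifest)


def _stage_concord(opt, out, state, manifest):
    if "mr_results" not in state or "meta_results" not in state:
        raise ConfigError("concord stage requires mr and meta stages (or their outputs)")
    sources: dict[str, dict[str, tuple[float, float]]] = {}
    # the MR column: the protein-weighted target estimate, one row per outcome
    mr = state["mr_results"].get("protein")
    if mr is not None:
        theta, se, _ = mr.single()
        sources["target_MR"] = {oc: (theta, se) for oc in state["meta_results"]}
    for oc, pooled in state["meta_results"].items():
        for compound, m in pooled.items():
            sources.setdefault(compound, {})[oc] = (m.effect, m.se)
    em = build_evidence_matrix(sources, floor=opt["floor"])
    res = cluster_matrix(
        em, transform=opt["transform"], metric=opt["metric"], linkage=opt["linkage"]
    )
    write_matrix(em, out / "evidence_matrix.tsv")
    _register(out / "evidence_matrix.tsv", manifest)
    (out / "row_dendrogram.nwk").write_text(res.row_newick() + "\n")
    (out / "col_dendrogram.nwk").write_text(res.col_newick() + "\n")
    _register(out / "row_dendrogram.nwk", manifest)
    _register(out / "col_dendrogram.nwk", manifest)
    manifest["stages"]["concord"] = {
        "rows_clustered": len(res.row_order), "cols_clustered": len(res.col_order),
        "rows_dropped": len(em.dropped_rows),
    }
    state["evidence"] = em
    state["clusters"] = res


def read_trials_frame(df: pd.DataFrame):
    """Validate an in-memory trial frame through the CSV reader's rules."""
    from targetmr.trial_meta import trials_from_frame

    return trials_from_frame(df)


def _load_inputs(cfg: dict) -> dict:
    """Read exposure/outcome/reference files named in the config (the
    no-simulation path for real summary-statistics runs)."""
    mr_cfg = cfg.get("mr")
    if not mr_cfg or "exposures" not in mr_cfg:
        raise ConfigError("mr stage without simulate requires mr.exposures file specs")
    exposures = {}
    for name, spec in mr_cfg["exposures"].items():
        exposures[name] = read_summary_stats(
            spec["path"], spec["columns"], trait_name=name,
            unit=spec.get("unit", ""), build=spec.get("build", "GRCh38"),
        )
    ospec = mr_cfg["outcome"]
    outcome = read_summary_stats(
        ospec["path"], ospec["columns"], trait_name=ospec.get("name", "outcome"),
        trait_type=ospec.get("type", "continuous"),
        unit=ospec.get("unit", ""), build=ospec.get("build", "GRCh38"),
    )
    reference = pd.read_csv(mr_cfg["reference"], sep="\t")
    return {"exposures": exposures, "outcome": outcome, "reference": reference}


def _flush_table(tbl: SummaryTable, path: Path, manifest: dict) -> None:
    write_summary_stats(tbl, path)
    _register(path, manifest)


def _register(path: Path, manifest: dict) -> None:
    manifest["files"][path.name] = _sha256(path)


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
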