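"""End-to-end orchestration: features -> scores -> survival tables -> strata.

``run_pipeline`` drives the whole analysis from a single config (dict or
YAML): simulate or ingest a cohort, univariate Cox per covariate and
endpoint (metric and binarized codings), multivariate Cox with named
covariate presets, optional stage-II subset reruns, the IQR-restricted
cutpoint search, the signature-ASP screen, and the combined ASP x EPPI
stratification, writing CSV reports plus a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .expr import (
    ExpressionMatrix,
    correlation_screen,
    eppi_score,
    example_eppi_model,
    filter_genes,
    normalize,
    size_factors,
)
from .surv import (
    ENDPOINTS,
    cox_fit,
    derive_endpoint,
    km_estimate,
    logrank,
    optimal_cutpoint,
    validate_fixed_cutoff,
)
from .synth import CohortConfig, simulate_cohort

__all__ = [
    "binarize_covariates",
    "combined_strata",
    "run_pipeline",
    "MULTIVARIATE_PRESETS",
    "DEFAULT_CUTOFFS",
]

log = logging.getLogger(__name__)

#: Prespecified (externally published) cutoffs; provenance "fixed".
DEFAULT_CUTOFFS = {"asp": 19.5, "eppi": 8.72, "eppi_stage2": 21.3}

#: Named multivariate covariate sets mirroring the two report blocks
#: (whole cohort: stage + histology + ASP; expression subset adds EPPI).
MULTIVARIATE_PRESETS = {
    "clinical_asp": ["stage_advanced", "histology_scc", "asp"],
    "clinical_asp_eppi": ["stage_advanced", "histology_scc", "asp", "eppi"],
}


def binarize_covariates(table: pd.DataFrame, cutoffs: dict[str, float]) -> pd.DataFrame:
    """Add ``<marker>_high`` indicator columns (strict ``marker > cutoff``).

    Cutoff provenance is attached in ``result.attrs["cutoffs"]``; a
    degenerate split (one empty group) is flagged in the log, not hidden.
    """
    out = table.copy()
    recorded = {}
    for marker, cutoff in cutoffs.items():
        if marker not in out.columns:
            raise ValueError(f"missing marker column {marker!r}")
        vals = out[marker].astype(float)
        high = (vals > float(cutoff)).where(vals.notna()).astype("boolean")
        col = f"{marker}_high"
        out[col] = high
        n_high = int(high.fillna(False).sum())
        n_low = int((~high.fillna(True)).sum())
        if n_high == 0 or n_low == 0:
            log.warning("degenerate split for %s at %.4g (low=%d, high=%d)", marker, cutoff, n_low, n_high)
        recorded[marker] = {"cutoff": float(cutoff), "n_low": n_low, "n_high": n_high}
    out.attrs["cutoffs"] = recorded
    return out


def _strata_label(asp_high, eppi_high) -> str:
    a = "ASPhigh" if asp_high else "ASPlow"
    if pd.isna(eppi_high):
        return f"{a}/NA"
    return f"{a}/{'EPPIhigh' if eppi_high else 'EPPIlow'}"


def combined_strata(
    table: pd.DataFrame,
    records: pd.DataFrame,
    mode: str = "four_group",
    asp_col: str = "asp_high",
    eppi_col: str = "eppi_high",
) -> dict:
    """Nested / crossed ASP x EPPI risk grouping with KM and log-rank.

    ``four_group``: cross of both markers; ``nested_within_asp_low`` and
    ``nested_within_eppi_high`` restrict to one stratum and split by the
    other marker.  Patients without an EPPI score stay in ASP-only
    analyses but are excluded from any EPPI split.  Empty comparisons are
    skipped with a log entry.
    """
    if mode not in ("four_group", "nested_within_asp_low", "nested_within_eppi_high"):
        raise ValueError(f"unknown stratification mode {mode!r}")
    merged = table.merge(records, on="patient_id", how="inner")
    asp_high = merged[asp_col].astype("boolean")
    eppi_high = merged[eppi_col].astype("boolean") if eppi_col in merged else pd.Series(pd.NA, index=merged.index, dtype="boolean")

    assignment = pd.DataFrame(
        {
            "patient_id": merged["patient_id"],
            "asp_group": np.where(asp_high.fillna(False), "high", "low"),
            "eppi_group": [
                "missing" if pd.isna(e) else ("high" if e else "low") for e in eppi_high
            ],
            "combined_label": [
                _strata_label(a, e) for a, e in zip(asp_high.fillna(False), eppi_high)
            ],
        }
    )

    if mode == "four_group":
        sel = merged[eppi_high.notna()]
        groups = assignment.loc[sel.index, "combined_label"]
    elif mode == "nested_within_asp_low":
        sel = merged[(~asp_high.fillna(True)) & eppi_high.notna()]
        groups = np.where(eppi_high.loc[sel.index], "EPPIhigh", "EPPIlow")
        groups = pd.Series(groups, index=sel.index)
    else:
        sel = merged[eppi_high.fillna(False)]
        groups = np.where(asp_high.loc[sel.index], "ASPhigh", "ASPlow")
        groups = pd.Series(groups, index=sel.index)

    km_tables: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for label in pd.unique(groups):
        sub = sel[groups == label]
        sizes[str(label)] = len(sub)
        if len(sub):
            km_tables[str(label)] = km_estimate(sub)
    result = {"assignment": assignment, "mode": mode, "group_sizes": sizes, "km": km_tables}
    nonempty = [g for g, n in sizes.items() if n > 0]
    if len(nonempty) >= 2 and sel["event"].sum() > 0:
        stat, p = logrank(sel, groups)
        result["logrank_stat"], result["logrank_p"] = stat, p
    else:
        log.warning("stratification %s: fewer than two nonempty groups; log-rank skipped", mode)
    return result


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

_UNIVARIATE_SPECS = [
    # (report name, column, coding builder)
    ("sex male", lambda df: (df["sex"] == "male").astype(float)),
    ("age > 70y", lambda df: (df["age"] > 70).astype(float)),
    ("UICC-stage > II", lambda df: (df["uicc_stage"] == "III").astype(float)),
    ("histology SCC", lambda df: (df["histology"] == "SCC").astype(float)),
    ("eppi", lambda df: df["eppi"].astype(float)),
    ("mtv", lambda df: df["mtv"].astype(float) if "mtv" in df else None),
    ("tlg", lambda df: df["tlg"].astype(float) if "tlg" in df else None),
    ("suv_max", lambda df: df["suv_max"].astype(float) if "suv_max" in df else None),
    ("asp", lambda df: df["asp"].astype(float)),
]


def _fit_row(name, endpoint, records, covariate):
    mask = covariate.notna() & records["time"].notna()
    rec = records[mask.to_numpy()]
    cov = covariate[mask]
    if rec["event"].sum() < 2 or cov.nunique() < 2:
        return {"covariate": name, "endpoint": endpoint, "hr": np.nan, "ci_low": np.nan,
                "ci_high": np.nan, "p": np.nan, "n": int(mask.sum()), "flags": "insufficient"}
    fit = cox_fit(rec, cov.to_numpy()[:, None], names=[name])
    row = fit.row(name)
    row["endpoint"] = endpoint
    return row


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute the configured analysis and write the report bundle.

    Config keys (all optional beyond ``seed``): ``cohort`` (CohortConfig
    fields for simulation) or ``cohort_csv``/``counts_tsv`` for user data,
    ``endpoints``, ``cutoffs``, ``multivariate_presets``, ``stage2``
    (bool: rerun on the UICC II subset), ``cutpoint_endpoints``.
    Any stage failure is recorded in the manifest's ``failures`` list and
    the remaining stages still run.
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    failures: list[str] = []
    seed = int(config.get("seed", 0))
    endpoints = [e.upper() for e in config.get("endpoints", ENDPOINTS)]
    cutoffs = {**DEFAULT_CUTOFFS, **config.get("cutoffs", {})}

    # ---- cohort -----------------------------------------------------------
    counts = None
    if "cohort_csv" in config:
        cohort = pd.read_csv(config["cohort_csv"])
        if "counts_tsv" in config:
            from .expr import load_counts_tsv

            counts = load_counts_tsv(config["counts_tsv"]).values
    else:
        cfg = CohortConfig(**{**config.get("cohort", {}), "seed": seed})
        cohort, counts = simulate_cohort(cfg)

    # ---- expression scores ------------------------------------------------
    eppi_measured = None
    screen = None
    if counts is not None:
        try:
            m = ExpressionMatrix(
                counts,
                stage="raw",
                cohorts=pd.Series(
                    cohort.set_index("patient_id")["cohort"], name="cohort"
                ),
            )
            filtered = filter_genes(m)
            norm = normalize(filtered, size_factors(filtered))
            model = example_eppi_model()
            eppi_measured = eppi_score(norm, model, min_gene_fraction=0.8)
            scores = eppi_measured.to_frame("EPPI")
            asp_series = cohort.set_index("patient_id")["asp"]
            cohort_series = cohort.set_index("patient_id")["cohort"]
            screen = correlation_screen(scores, asp_series, cohort_series)
            screen.to_csv(out_dir / "screen.csv", index=False)
            cohort = cohort.merge(
                eppi_measured.rename("eppi_measured"),
                left_on="patient_id",
                right_index=True,
                how="left",
            )
        except Exception as exc:  # pragma: no cover - failure path
            failures.append(f"expression: {exc}")
            log.exception("expression stage failed")

    # ---- per-endpoint records --------------------------------------------
    records = {}
    for ep in endpoints:
        records[ep] = derive_endpoint(cohort, ep)

    table = binarize_covariates(
        cohort, {"asp": cutoffs["asp"], "eppi": cutoffs["eppi"]}
    )

    # ---- univariate Cox ---------------------------------------------------
    for ep in endpoints:
        rec = records[ep].merge(cohort, on="patient_id")
        rows = []
        for name, builder in _UNIVARIATE_SPECS:
            cov = builder(rec)
            if cov is None:
                continue
            try:
                rows.append(_fit_row(name, ep, rec[["time", "event"]], cov))
            except Exception as exc:
                failures.append(f"univariate {name}/{ep}: {exc}")
        pd.DataFrame(rows).to_csv(out_dir / f"univariate_{ep}.csv", index=False)

    # ---- multivariate Cox -------------------------------------------------
    presets = config.get("multivariate_presets", list(MULTIVARIATE_PRESETS))
    for preset in presets:
        cols = MULTIVARIATE_PRESETS.get(preset, preset if isinstance(preset, list) else None)
        if cols is None:
            failures.append(f"multivariate: unknown preset {preset!r}")
            continue
        name = preset if isinstance(preset, str) else "_".join(cols)
        ep = endpoints[0]
        rec = records[ep].merge(cohort, on="patient_id")
        design = pd.DataFrame(
            {
                "stage_advanced": (rec["uicc_stage"] == "III").astype(float),
                "histology_scc": (rec["histology"] == "SCC").astype(float),
                "asp": rec["asp"].astype(float),
                "eppi": rec["eppi"].astype(float),
            }
        )[cols]
        keep = design.notna().all(axis=1)
        try:
            fit = cox_fit(rec[keep.to_numpy()][["time", "event"]], design[keep])
            rows = [dict(fit.row(c), endpoint=ep) for c in cols]
            pd.DataFrame(rows).to_csv(out_dir / f"multivariate_{name}.csv", index=False)
        except Exception as exc:
            failures.append(f"multivariate {name}: {exc}")

    # ---- cutpoint search and fixed-cutoff validation ----------------------
    cut_rows = []
    for ep in config.get("cutpoint_endpoints", ["PFS"]):
        ep = ep.upper()
        rec = records[ep].merge(cohort, on="patient_id")
        try:
            res = optimal_cutpoint(
                rec["asp"], rec[["time", "event"]], marker_name="asp", endpoint=ep
            )
            cut_rows.append(
                {
                    "marker": "asp",
                    "endpoint": ep,
                    "cutoff": res.cutoff,
                    "hr": float(res.fit.hr[0]),
                    "p": float(res.fit.p[0]),
                    "iqr_low": res.iqr[0],
                    "iqr_high": res.iqr[1],
                    "n_candidates": res.n_candidates,
                    "provenance": "optimized",
                }
            )
        except Exception as exc:
            failures.append(f"cutpoint asp/{ep}: {exc}")
    try:
        rec = records["PFS"].merge(cohort, on="patient_id")
        val = validate_fixed_cutoff(rec["asp"], rec[["time", "event"]], cutoffs["asp"])
        cut_rows.append(
            {
                "marker": "asp",
                "endpoint": "PFS",
                "cutoff": cutoffs["asp"],
                "hr": float(val["fit"].hr[0]),
                "p": float(val["fit"].p[0]),
                "iqr_low": np.nan,
                "iqr_high": np.nan,
                "n_candidates": 0,
                "provenance": "fixed",
            }
        )
    except Exception as exc:
        failures.append(f"fixed cutoff validation: {exc}")
    pd.DataFrame(cut_rows).to_csv(out_dir / "cutpoints.csv", index=False)

    # ---- combined stratification -----------------------------------------
    strata_summary = {}
    for mode in ("four_group", "nested_within_asp_low", "nested_within_eppi_high"):
        try:
            res = combined_strata(table, records["PFS"], mode=mode)
            strata_summary[mode] = {
                "group_sizes": res["group_sizes"],
                "logrank_p": res.get("logrank_p"),
            }
            km_rows = []
            for label, km in res["km"].items():
                km = km.copy()
                km.insert(0, "group", label)
                km_rows.append(km)
            if km_rows:
                pd.concat(km_rows).to_csv(out_dir / f"km_{mode}.csv", index=False)
        except Exception as exc:
            failures.append(f"strata {mode}: {exc}")

    # ---- stage II subset --------------------------------------------------
    if config.get("stage2", True):
        sub = cohort[cohort["uicc_stage"] == "II"]
        if len(sub) == 0:
            log.warning("no UICC stage II patients; subset analysis skipped")
        else:
            for ep in endpoints:
                rec = derive_endpoint(sub, ep).merge(sub, on="patient_id")
                rows = []
                for name, builder in _UNIVARIATE_SPECS:
                    if name == "UICC-stage > II":
                        continue
                    cov = builder(rec)
                    if cov is None:
                        continue
                    try:
                        rows.append(_fit_row(name, ep, rec[["time", "event"]], cov))
                    except Exception as exc:
                        failures.append(f"stage2 univariate {name}/{ep}: {exc}")
                pd.DataFrame(rows).to_csv(out_dir / f"univariate_stage2_{ep}.csv", index=False)

    # ---- manifest ---------------------------------------------------------
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": cfg_hash,
        "n_patients": int(len(cohort)),
        "endpoints": endpoints,
        "cutoffs": table.attrs.get("cutoffs", {}),
        "strata": strata_summary,
        "failures": failures,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    return manifest
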