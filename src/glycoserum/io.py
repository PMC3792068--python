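"""Table readers/writers, pipeline configuration and orchestration.

Delimited tables are comma-separated with a tab-separated fallback
auto-detected from the header line.  Abundance matrices are samples x
glycans with the first column holding sample IDs and glycan columns
addressed either by composition code ("5402") or integer peak label
(2378); both resolve against the reference panel.

``run_pipeline`` ties the stages together in the order the analysis
runs: classification -> differential screen -> ratio marker -> pathway
export -> aggregate bootstrap -> clinical strata -> survival, writing
every report into one output directory.  All randomness flows from the
single configured seed, so a rerun with the same inputs is
byte-identical.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, network, stats, survival as surv
from .cohort import reference_panel
from .core import GlycanPanel

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_abundance_matrix",
    "read_metadata",
    "write_table",
    "run_pipeline",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if ("\t" in header and "," not in header) else ","


def _read_rows(path: Path) -> tuple[list[str], list[list[str]], str]:
    sep = _sniff_sep(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        rows = [row for row in reader]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header, body = rows[0], rows[1:]
    for lineno, row in enumerate(body, start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, header has {len(header)})"
            )
    return header, body, sep


def read_abundance_matrix(path: str | Path, panel: GlycanPanel | None = None) -> pd.DataFrame:
    """Read a samples x glycans abundance table (pmol/uL).

    Glycan columns may use codes or integer labels; with a panel supplied
    (default: the reference panel) they are resolved to codes and unknown
    identifiers raise with the full list.  Duplicate sample IDs or glycan
    columns, non-numeric and negative abundances are rejected.
    """
    path = Path(path)
    panel = panel or reference_panel()
    header, body, _ = _read_rows(path)
    glycan_cols = header[1:]
    unknown = [c for c in glycan_cols if c not in panel]
    if unknown:
        raise KeyError(f"{path}: glycan identifiers not in panel: {unknown}")
    codes = [panel.resolve(c) for c in glycan_cols]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"{path}: duplicate glycan columns (after label/code resolution): {dupes}")
    ids = [row[0] for row in body]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate sample IDs: {dupes}")
    values = np.empty((len(body), len(codes)))
    for i, row in enumerate(body):
        for j, cell in enumerate(row[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric abundance {cell!r} at sample {ids[i]!r}, "
                    f"glycan {glycan_cols[j]}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"{path}: negative abundance {v} at sample {ids[i]!r}, glycan {glycan_cols[j]}"
                )
            values[i, j] = v
    return pd.DataFrame(values, index=pd.Index(ids, name="sample_id"), columns=codes)


#: dtypes for recognised metadata columns
_META_TYPES = {
    "group": "string",
    "extent": "string",
    "cai": "Int64",
    "mayo": "Int64",
    "steroid_refractory": "Int64",
    "time_months": "float64",
    "event": "Int64",
}


def read_metadata(
    path: str | Path,
    matrix: pd.DataFrame | None = None,
    required: tuple[str, ...] = ("group",),
) -> pd.DataFrame:
    """Read the sample metadata table, typed, indexed by sample ID.

    Missing required columns raise by name; with a matrix supplied, any
    ID mismatch raises with the set difference in both directions.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required metadata column(s): {missing}")
    for col, dtype in _META_TYPES.items():
        if col in df.columns:
            df[col] = df[col].astype(dtype)
    if matrix is not None:
        only_meta = sorted(set(df.index) - set(matrix.index))
        only_matrix = sorted(set(matrix.index) - set(df.index))
        if only_meta or only_matrix:
            raise ValueError(
                f"{path}: sample IDs disagree with matrix "
                f"(metadata-only: {only_meta}, matrix-only: {only_matrix})"
            )
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    df.to_csv(path, index=index)
    return path


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end analysis settings (defaults follow the study design)."""

    matrix_path: str | Path
    metadata_path: str | Path
    out_dir: str | Path
    alpha: float = 0.05
    entry_p: float = 0.1
    bootstrap_b: int = 10_000
    seed: int = 0
    cutoff: str | float = "median"
    collinearity_r: float = 0.7
    case: str = "UC"
    control: str = "HLT"
    strata: tuple[str, ...] = ("extent", "cai", "mayo", "steroid_refractory")
    ties: str = "breslow"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.entry_p <= 1:
            raise ValueError(f"entry_p must be in (0, 1], got {self.entry_p}")
        if self.bootstrap_b < 100:
            raise ValueError(f"bootstrap B must be >= 100, got {self.bootstrap_b}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config; keyword overrides (e.g. CLI flags) win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "strata" in raw and not isinstance(raw["strata"], tuple):
            raw["strata"] = tuple(raw["strata"])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def _stratum_series(metadata: pd.DataFrame, name: str) -> tuple[pd.Series, str]:
    """Binary clinical stratum from a metadata column.

    extent: total vs left-sided colitis; cai: > 10 vs <= 10; mayo:
    endoscopic score 3 vs 1-2 (score 0 excluded); steroid_refractory:
    yes vs no.
    """
    if name not in metadata.columns:
        raise ValueError(f"metadata lacks column {name!r} required for stratum analysis")
    col = metadata[name]
    if name == "extent":
        s = col.map({"total": True, "left-sided": False})
        return s, "total_colitis"
    if name == "cai":
        return (col > 10).mask(col.isna()), "cai_gt10"
    if name == "mayo":
        s = pd.Series(pd.NA, index=col.index, dtype="boolean")
        s[col == 3] = True
        s[(col == 1) | (col == 2)] = False
        return s, "mayo_3"
    if name == "steroid_refractory":
        return (col == 1).mask(col.isna()), "steroid_refractory"
    raise ValueError(f"no stratum rule for column {name!r}")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis and write all report tables.

    Returns a mapping of report names to written paths; also writes
    ``run_log.txt`` echoing the seed and parameters.  Raises
    :class:`PipelineError` naming the failing stage.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = reference_panel()
    paths: dict[str, Path] = {}
    loglines: list[str] = []

    matrix = _stage("read_matrix")(read_abundance_matrix)(cfg.matrix_path, panel)
    metadata = _stage("read_metadata")(read_metadata)(cfg.metadata_path, matrix)
    groups = metadata["group"].astype(str)

    # --- panel & classification -------------------------------------------
    paths["panel"] = write_table(panel.to_frame(), out / "panel.csv", index=False)
    report = _stage("classify")(classify.classification_report)(panel)
    paths["classification"] = write_table(report, out / "classification.csv", index=False)

    # --- differential screen & ratio marker -------------------------------
    diff = _stage("differential")(stats.per_glycan_differential)(
        matrix, groups, case=cfg.case, control=cfg.control, alpha=cfg.alpha, panel=panel
    )
    paths["differential"] = write_table(diff, out / "differential.csv")
    marker = _stage("ratio_marker")(stats.select_ratio_marker)(diff, matrix, groups, panel)
    marker_df = pd.DataFrame(
        [
            {
                "numerator": marker.numerator,
                "numerator_label": marker.numerator_label,
                "denominator": marker.denominator,
                "denominator_label": marker.denominator_label,
                "auroc": marker.auroc,
            }
        ]
    )
    paths["marker"] = write_table(marker_df, out / "marker.csv", index=False)
    sample_table = metadata.copy()
    sample_table["marker_ratio"] = marker.values
    loglines.append(f"ratio marker: {marker.name} (AUROC {marker.auroc:.4f})")

    # --- pathway network ---------------------------------------------------
    def _pathway():
        g = network.build_network(panel)
        network.annotate_fold_change(g, matrix, groups, case=cfg.case, control=cfg.control)
        written = network.export_graph(g, out / "pathway.graphml", fmt="graphml")
        written += network.export_graph(g, out / "pathway.sif", fmt="sif")
        summary = network.class_summary(g)
        written.append(write_table(summary, out / "pathway_class_summary.csv", index=False))
        return written

    for p in _stage("pathway")(_pathway)():
        paths[p.name] = p

    # --- aggregate classes: totals and bootstrap confirmation --------------
    def _aggregates():
        agg = pd.DataFrame(index=matrix.index)
        for name in (
            "all", "high-mannose", "hybrid", "complex", "sialylated", "fucosylated",
            "agalactosyl_bi", "highly_sialylated_multibranched",
        ):
            agg[name] = classify.aggregate_abundance(matrix, panel, name)
        rows = []
        rng = np.random.default_rng(cfg.seed)
        for name in ("complex", "sialylated"):
            boot = stats.bootstrap_group_means(
                agg[name].to_numpy(), groups.to_numpy(), B=cfg.bootstrap_b, seed=rng
            )
            rows.append(
                {
                    "aggregate": name,
                    f"point_{cfg.case}": boot["point_estimates"].get(cfg.case),
                    f"point_{cfg.control}": boot["point_estimates"].get(cfg.control),
                    "p": boot["p"],
                    "B": boot["B"],
                }
            )
        return agg, pd.DataFrame(rows)

    agg, boot_df = _stage("aggregates")(_aggregates)()
    paths["aggregates"] = write_table(agg, out / "aggregates.csv")
    paths["bootstrap"] = write_table(boot_df, out / "bootstrap.csv", index=False)
    sample_table["hs_multibranched"] = agg["highly_sialylated_multibranched"]

    # --- clinical strata ----------------------------------------------------
    def _strata():
        uc = metadata[groups == cfg.case]
        rows = []
        rng = np.random.default_rng(cfg.seed + 1)
        for colname in cfg.strata:
            series, label = _stratum_series(uc, colname)
            for value_name, values in (
                ("marker_ratio", marker.values),
                ("hs_multibranched", agg["highly_sialylated_multibranched"]),
            ):
                res = stats.strata_compare(
                    values.reindex(uc.index).dropna(),
                    series.astype("boolean"),
                    B=cfg.bootstrap_b,
                    seed=rng,
                )
                hi, lo = res["means"].get("True"), res["means"].get("False")
                boot = res["bootstrap"]["point_estimates"]
                rows.append(
                    {
                        "stratum": label,
                        "quantity": value_name,
                        "n_true": res["n"].get("True"),
                        "n_false": res["n"].get("False"),
                        "mean_true": hi,
                        "mean_false": lo,
                        "t": res["t"],
                        "p": res["p"],
                        "boot_true": boot.get("True"),
                        "boot_false": boot.get("False"),
                        "boot_p": res["bootstrap"]["p"],
                    }
                )
        return pd.DataFrame(rows)

    paths["strata"] = write_table(_stage("strata")(_strata)(), out / "strata.csv", index=False)

    # --- survival -----------------------------------------------------------
    def _survival():
        uc = metadata[groups == cfg.case]
        required = [c for c in ("time_months", "event") if c not in uc.columns]
        if required:
            raise ValueError(f"metadata lacks survival column(s): {required}")
        sdata = uc.dropna(subset=["time_months", "event"])
        time = sdata["time_months"].to_numpy(dtype=float)
        event = sdata["event"].to_numpy(dtype=float)
        mvals = marker.values.reindex(sdata.index).dropna()
        sdata = sdata.loc[mvals.index]
        time = sdata["time_months"].to_numpy(dtype=float)
        event = sdata["event"].to_numpy(dtype=float)

        high, cutoff = surv.dichotomize(mvals, cfg.cutoff)
        loglines.append(f"marker cutoff ({cfg.cutoff}): {cutoff:.4f}")
        km = surv.km_by_group(time, event, np.where(high, "high", "low"))
        km_df = pd.concat(
            [df.assign(group=g) for g, df in sorted(km.items())], ignore_index=True
        )
        chi2, logrank_p = surv.logrank_test(time, event, high.to_numpy())
        loglines.append(f"log-rank: chi2={chi2:.4f} p={logrank_p:.6f}")

        covs = pd.DataFrame(index=sdata.index)
        covs["marker_ratio_high"] = high.astype(int)
        hs_high, _ = surv.dichotomize(agg["highly_sialylated_multibranched"].reindex(sdata.index), cfg.cutoff)
        covs["hs_multibranched_high"] = hs_high.astype(int)
        for colname in cfg.strata:
            series, label = _stratum_series(sdata, colname)
            covs[label] = series.astype("boolean").astype("Int64")
        covs = covs.dropna(axis=1, how="any").astype(float)
        # drop covariates that are constant in this (sub)cohort
        covs = covs.loc[:, covs.nunique() > 1]

        uni_table, selected = surv.univariate_screen(time, event, covs, cfg.entry_p, ties=cfg.ties)
        results = [("univariate", uni_table)]
        if len(selected) >= 1:
            multi = surv.multivariate_cox(
                time, event, covs[selected],
                collinearity_r=cfg.collinearity_r, ties=cfg.ties,
                univariate_p=uni_table["p"],
            )
            loglines.append(f"multivariate dropped for collinearity: {list(multi.dropped)}")
            results.append(("multivariate", multi.summary))
        sens, spec = surv.diagnostic_accuracy(high.to_numpy(), event.astype(bool))
        diag = pd.DataFrame(
            [{"cutoff_rule": str(cfg.cutoff), "cutoff": cutoff,
              "sensitivity": sens, "specificity": spec}]
        )
        cox_df = pd.concat(
            [t.assign(analysis=nm) for nm, t in results]
        ).reset_index().set_index(["analysis", "covariate"])
        lr_df = pd.DataFrame([{"chi2": chi2, "p": logrank_p, "cutoff": cutoff}])
        return km_df, lr_df, cox_df, diag

    km_df, lr_df, cox_df, diag = _stage("survival")(_survival)()
    paths["km_curves"] = write_table(km_df, out / "km_curves.csv", index=False)
    paths["logrank"] = write_table(lr_df, out / "logrank.csv", index=False)
    paths["cox"] = write_table(cox_df, out / "cox.csv")
    paths["diagnostic"] = write_table(diag, out / "diagnostic.csv", index=False)
    paths["samples"] = write_table(sample_table, out / "samples.csv")

    # --- run log ------------------------------------------------------------
    from . import __version__

    lines = [
        f"glycoserum {__version__}",
        f"seed: {cfg.seed}",
        "parameters:",
    ]
    for f in dataclasses.fields(cfg):
        lines.append(f"  {f.name}: {getattr(cfg, f.name)}")
    lines += ["stages:"] + [f"  {ln}" for ln in loglines]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
    paths["run_log"] = out / "run_log.txt"
    return paths
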