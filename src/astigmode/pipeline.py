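"""Eye-record I/O, run configuration, and the end-to-end analysis pipeline.

The interchange format is a wide CSV, one row per eye, with mode-keyed
preoperative astigmatism columns (``pre_<geometry>_<center>_<d>mm_mag`` /
``_axis`` for the 16 analysis modes), the postoperative total corneal
astigmatism, the spectacle-plane manifest residual astigmatism, and the
biometry and IOL fields needed for the corneal-plane conversions.  No
standard ophthalmic exchange format covers device mode tables, so the
column dictionary below is the contract.

``run_pipeline`` executes: plane conversion → SIA → actual corneal
astigmatism → per-mode prediction errors → grouped summaries → paired
mode comparisons, deterministically for a fixed configuration, and every
output table carries the hash of the resolved configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Astigmatism
from .modes import ALL_MODES
from .outcomes import (
    SIGNS_CONSISTENT,
    SIGNS_LITERAL,
    actual_corneal_astigmatism,
    compute_sia,
    prediction_error,
    summarize_modes,
)
from .planes import BiometryContext, residual_to_corneal_plane, toric_to_corneal_plane
from .stats import compare_modes

logger = logging.getLogger("astigmode")

__all__ = [
    "RunConfig",
    "REQUIRED_COLUMNS",
    "read_eye_records",
    "compute_prediction_errors",
    "run_pipeline",
    "write_outputs",
]

_BIOMETRY_COLUMNS = (
    "post_mag", "post_axis", "residual_mag", "residual_axis",
    "k_net", "elp_mm", "iol_cylinder", "iol_axis",
)

#: Columns every eye-record CSV must provide.
REQUIRED_COLUMNS: tuple[str, ...] = (
    ("eye_id",)
    + tuple(f"pre_{m.key}_{f}" for m in ALL_MODES for f in ("mag", "axis"))
    + _BIOMETRY_COLUMNS
)

_MAG_COLUMNS = tuple(c for c in REQUIRED_COLUMNS if c.endswith("_mag")) + (
    "iol_cylinder",
)
_AXIS_COLUMNS = tuple(c for c in REQUIRED_COLUMNS if c.endswith("_axis")) + (
    "iol_axis",
)


@dataclass(frozen=True)
class RunConfig:
    """Resolved knobs of one analysis run (serializable; hashed into outputs).

    signs_mode
        ``"consistent"`` → (+1, −1, +1) composition (residual − SIA +
        toric), the optically closing back-solve; ``"literal"`` → the
        unsigned (+1, +1, +1) sum, kept for fidelity comparisons.
    sia_mode
        Analysis-mode key whose preoperative column pairs with the single
        postoperative measurement to form the SIA.
    subgroup_policy
        Test reported for the bowtie-type subgroup comparisons (the
        published tables use the paired t there, Wilcoxon elsewhere).
    """

    signs_mode: str = "consistent"
    cylinder_conversion: str = "meridional"
    vertex_distance_m: float = 0.012
    ring_tolerance_mm: float | None = None
    bowtie_contrast_d: float = 0.25
    comparison_policy: str = "wilcoxon"
    subgroup_policy: str = "paired_t"
    sia_mode: str = "zone_apex_3mm"
    interpolation: str = "none"
    seed: int = 0

    @property
    def signs(self) -> tuple[int, int, int]:
        if self.signs_mode == "consistent":
            return SIGNS_CONSISTENT
        if self.signs_mode == "literal":
            return SIGNS_LITERAL
        raise ValueError(f"unknown signs_mode {self.signs_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_eye_records(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate an eye-record CSV.

    Returns ``(accepted, rejects)``; malformed rows land in ``rejects``
    with a ``reject_reason`` column, so that accepted + rejected row
    counts always equal the input row count.  Axes outside [0, 180) are
    normalized modulo 180 with a logged warning, not rejected.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")

    reasons = pd.Series("", index=df.index, dtype=object)
    for col in REQUIRED_COLUMNS:
        bad = df[col].isna() & (reasons == "")
        reasons[bad] = f"missing {col}"
    for col in _MAG_COLUMNS:
        bad = (df[col] < 0) & (reasons == "")
        reasons[bad] = f"negative {col}"

    normalized = 0
    for col in _AXIS_COLUMNS:
        out_of_range = df[col].notna() & ((df[col] < 0) | (df[col] >= 180.0))
        if out_of_range.any():
            df.loc[out_of_range, col] = df.loc[out_of_range, col] % 180.0
            normalized += int(out_of_range.sum())
    if normalized:
        logger.warning("normalized %d axis values into [0, 180)", normalized)

    accepted = df[reasons == ""].reset_index(drop=True)
    rejects = df[reasons != ""].copy()
    rejects["reject_reason"] = reasons[reasons != ""]
    rejects = rejects.reset_index(drop=True)
    logger.info("read %d eye records: %d accepted, %d rejected",
                len(df), len(accepted), len(rejects))
    return accepted, rejects


def compute_prediction_errors(records: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Per-eye, per-mode prediction errors (long table).

    For each eye: vertex-convert the manifest residual, form the SIA from
    the configured mode, convert the toric cylinder through the vergence
    chain at the recorded postoperative IOL axis, compose the actual
    corneal astigmatism with the configured signs, and difference it
    against each of the 16 preoperative measurements.
    """
    rows = []
    carry = [c for c in ("symmetry", "bowtie_type", "group") if c in records.columns]
    for rec in records.itertuples(index=False):
        r = rec._asdict()
        ctx = BiometryContext(
            k_net=r["k_net"], elp_mm=r["elp_mm"],
            vertex_distance_m=config.vertex_distance_m,
        )
        residual = Astigmatism(
            residual_to_corneal_plane(r["residual_mag"], config.vertex_distance_m),
            r["residual_axis"],
        )
        pre_sia = Astigmatism(
            r[f"pre_{config.sia_mode}_mag"], r[f"pre_{config.sia_mode}_axis"]
        )
        sia = compute_sia(pre_sia, Astigmatism(r["post_mag"], r["post_axis"]))
        toric_mag = (
            toric_to_corneal_plane(r["iol_cylinder"], ctx, config.cylinder_conversion)
            if r["iol_cylinder"] > 0 else 0.0
        )
        toric = Astigmatism(toric_mag, r["iol_axis"] if toric_mag > 0 else 0.0)
        actual = actual_corneal_astigmatism(residual, sia, toric, config.signs)
        for spec in ALL_MODES:
            measured = Astigmatism(r[f"pre_{spec.key}_mag"], r[f"pre_{spec.key}_axis"])
            err = prediction_error(actual, measured)
            row = {
                "eye_id": r["eye_id"],
                "mode": spec.key,
                "error_magnitude": err.magnitude,
                "error_axis": err.axis,
                "actual_mag": actual.magnitude,
                "actual_axis": actual.axis,
                "sia_mag": sia.magnitude,
                "sia_axis": sia.axis,
            }
            for c in carry:
                row[c] = r[c]
            rows.append(row)
    return pd.DataFrame(rows)


def _abs_error_matrix(errors: pd.DataFrame) -> pd.DataFrame:
    """Eyes × modes matrix of absolute errors, eye order preserved."""
    return errors.pivot(index="eye_id", columns="mode", values="error_magnitude")


def _paired_rows(mat: pd.DataFrame, pairs: list[tuple[str, str, str]],
                 policy: str, group: str) -> list[dict]:
    rows = []
    for label, key_a, key_b in pairs:
        a = mat[key_a].to_numpy()
        b = mat[key_b].to_numpy()
        cmp = compare_modes(a, b, policy=policy)
        rows.append(
            {
                "group": group,
                "comparison": label,
                "mode_a": key_a,
                "mode_b": key_b,
                "n": cmp.n,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "test_used": cmp.test_used,
                "p_value": cmp.p_value,
                "wilcoxon_p": cmp.wilcoxon_p,
                "t_p": cmp.t_p,
                "normality_p": cmp.normality_p,
                "degenerate": cmp.degenerate,
            }
        )
    return rows


def _comparison_pairs() -> dict[str, list[tuple[str, str, str]]]:
    diameters = (2, 3, 4, 5)
    apex_vs_pupil = [
        (f"{g}_{d}mm_apex_vs_pupil", f"{g}_apex_{d}mm", f"{g}_pupil_{d}mm")
        for g in ("ring", "zone") for d in diameters
    ]
    ring_vs_zone = [
        (f"{c}_{d}mm_ring_vs_zone", f"ring_{c}_{d}mm", f"zone_{c}_{d}mm")
        for c in ("apex", "pupil") for d in diameters
    ]
    ring_vs_zone_apex = [
        (f"apex_{d}mm_ring_vs_zone", f"ring_apex_{d}mm", f"zone_apex_{d}mm")
        for d in diameters
    ]
    return {
        "overall": apex_vs_pupil + ring_vs_zone,
        "subgroup": ring_vs_zone_apex,
    }


def run_pipeline(
    records: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict:
    """Execute the full analysis on validated eye records.

    Returns a dict of DataFrames — the long ``errors`` table, the overall
    per-mode ``summary``, ``summary_by_group`` when grouping columns
    (``symmetry`` / ``bowtie_type``) are present, and the paired
    ``comparisons`` (apex vs pupil and ring vs zone overall; apex-centered
    ring vs zone within each group) — plus the resolved config and its
    hash.  Deterministic given records + config.
    """
    config = config or RunConfig()
    if len(records) == 0:
        raise ValueError("no eye records to analyze")
    logger.info("pipeline start: %d eyes, config %s", len(records), config.hash)

    errors = compute_prediction_errors(records, config)
    summary = summarize_modes(errors)
    mat = _abs_error_matrix(errors)
    pairs = _comparison_pairs()

    min_pairs = 6
    comparison_rows = []
    if len(mat) >= min_pairs:
        comparison_rows += _paired_rows(mat, pairs["overall"], config.comparison_policy, "overall")
    else:
        logger.warning("only %d eyes (< %d): overall paired tests skipped", len(mat), min_pairs)

    group_summaries = []
    for col, policy in (("symmetry", config.comparison_policy),
                        ("bowtie_type", config.subgroup_policy)):
        if col not in errors.columns:
            continue
        for value, sub in errors.groupby(col):
            if not isinstance(value, str) or value in ("", "none"):
                continue
            s = summarize_modes(sub)
            s.insert(0, "group", value)
            group_summaries.append(s)
            sub_mat = _abs_error_matrix(sub)
            if len(sub_mat) >= min_pairs:
                comparison_rows += _paired_rows(sub_mat, pairs["subgroup"], policy, value)
            else:
                logger.warning("group %s has %d eyes (< %d): paired tests skipped",
                               value, len(sub_mat), min_pairs)

    results = {
        "errors": errors,
        "summary": summary,
        "summary_by_group": (
            pd.concat(group_summaries, ignore_index=True) if group_summaries else pd.DataFrame()
        ),
        "comparisons": pd.DataFrame(comparison_rows),
        "config": config.to_dict(),
        "config_hash": config.hash,
        "flags": {},
    }
    if config.signs_mode == "literal":
        results["flags"]["literal_sign_composition"] = (
            "literal (+,+,+) vector sum selected: the back-calculated actual "
            "astigmatism does not recover a noiseless truth whenever SIA != 0"
        )
    logger.info("pipeline done: %d comparisons", len(results["comparisons"]))
    return results


def write_outputs(results: dict, outdir: str | Path) -> list[Path]:
    """Write every result table as CSV (config hash in a leading comment
    line) plus the resolved configuration as JSON.  Diopter columns are
    rounded to 0.01 on output; full precision stays in memory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    header = f"# config_hash: {results['config_hash']}\n"
    for name in ("errors", "summary", "summary_by_group", "comparisons"):
        df = results[name]
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            out = df.copy()
            for col in out.columns:
                if out[col].dtype.kind == "f":
                    out[col] = out[col].round(4)
            out.to_csv(fh, index=False)
        written.append(path)
    cfg_path = outdir / "run_config.json"
    cfg_path.write_text(
        json.dumps({"hash": results["config_hash"], **results["config"],
                    "flags": results["flags"]}, indent=1)
    )
    written.append(cfg_path)
    return written
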