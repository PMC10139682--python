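"""Trial dataset schema and file I/O.

The canonical on-disk layout is a wide CSV: one row per participant with an
``id`` column, an ``arm`` column (``intervention`` / ``control``), optional
baseline covariate columns, and two score columns per instrument
(``EPDS_T0``, ``EPDS_T1``, ...).  Missing cells are empty by default; an
alternate sentinel such as ``"NA"`` is accepted on read.  Scores are stored
as reals even for integer-scored instruments because the estimator is
distribution-based; datasets generated without discretization carry a
``continuous`` flag that suppresses range validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .lcs import INSTRUMENTS

ARMS = ("intervention", "control")
WAVES = ("T0", "T1")

#: Baseline covariates the descriptive layer knows about, with their kind.
COVARIATES = {
    "age": "numeric",
    "parity": "categorical",
    "marital_status": "categorical",
    "education": "categorical",
    "employment": "categorical",
    "income": "categorical",
    "residence": "categorical",
    "infant_age": "numeric",
    "infant_sex": "categorical",
    "pdpi_r": "numeric",
}


class SchemaError(ValueError):
    """Raised when a file does not conform to the trial schema."""


class IntegrityError(ValueError):
    """Raised on duplicate identifiers or other integrity violations."""


@dataclass(frozen=True)
class InstrumentSpec:
    """Scoring range and direction of one self-report instrument."""

    name: str
    score_min: float
    score_max: float
    direction: str  # "higher_worse" | "higher_better"

    def __post_init__(self):
        if not self.score_min < self.score_max:
            raise SchemaError(f"{self.name}: score_min must be below score_max")
        if self.direction not in ("higher_worse", "higher_better"):
            raise SchemaError(f"{self.name}: unknown direction {self.direction!r}")


#: Published total-score ranges: EPDS 0-30, HADS-A 0-21, DERS-SF 18-90,
#: SCS-SF 12-60, CompACT 0-108.  Symptom scales score higher = worse; the
#: self-compassion and flexibility scales higher = better.
DEFAULT_SCHEMA = (
    InstrumentSpec("EPDS", 0, 30, "higher_worse"),
    InstrumentSpec("HADS_A", 0, 21, "higher_worse"),
    InstrumentSpec("DERS_SF", 18, 90, "higher_worse"),
    InstrumentSpec("SCS_SF", 12, 60, "higher_better"),
    InstrumentSpec("COMPACT", 0, 108, "higher_better"),
)


def score_columns(instruments=INSTRUMENTS) -> list[str]:
    return [f"{inst}_{w}" for inst in instruments for w in WAVES]


@dataclass
class TrialDataset:
    """A two-arm, two-wave trial table plus its instrument schema.

    ``data`` holds one row per participant; score cells use NaN for missing.
    ``provenance`` records whether the table was observed or synthesized
    (and, if synthetic, the seed and config hash).
    """

    data: pd.DataFrame
    schema: tuple = DEFAULT_SCHEMA
    provenance: dict = field(default_factory=lambda: {"source": "observed"})
    continuous: bool = False

    def __post_init__(self):
        if "arm" not in self.data.columns or "id" not in self.data.columns:
            raise SchemaError("dataset requires 'id' and 'arm' columns")
        bad = set(self.data["arm"].unique()) - set(ARMS)
        if bad:
            raise SchemaError(f"unknown arm label(s): {sorted(bad)}")
        if self.data["id"].duplicated().any():
            dupes = self.data.loc[self.data["id"].duplicated(), "id"].tolist()
            raise IntegrityError(f"duplicate participant id(s): {dupes[:5]}")

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def instruments(self) -> list[str]:
        return [spec.name for spec in self.schema]

    def arm_counts(self) -> dict:
        counts = self.data["arm"].value_counts()
        return {arm: int(counts.get(arm, 0)) for arm in ARMS}

    def score_matrix(self, arm: str | None = None, instruments=None) -> np.ndarray:
        """(n, 2k) array of scores in canonical order (T0 block then T1 block
        per instrument-major pairs: inst1_T0, inst1_T1 would interleave, so
        the layout is [inst_T0 for all inst] + [inst_T1 for all inst])."""
        instruments = list(instruments or self.instruments)
        df = self.data if arm is None else self.data[self.data["arm"] == arm]
        cols = [f"{i}_T0" for i in instruments] + [f"{i}_T1" for i in instruments]
        return df[cols].to_numpy(dtype=float)

    def arm_matrices(self, instruments=None) -> list[np.ndarray]:
        """Score matrices for (intervention, control), in that order."""
        return [self.score_matrix(arm, instruments) for arm in ARMS]

    def missingness_rates(self, wave: str = "T1") -> dict:
        return {
            inst: float(self.data[f"{inst}_{wave}"].isna().mean())
            for inst in self.instruments
        }

    def subset(self, mask, note: str = "subset") -> "TrialDataset":
        prov = dict(self.provenance)
        prov["filter"] = f"{prov.get('filter', '')}+{note}".lstrip("+")
        return replace(self, data=self.data[np.asarray(mask)].reset_index(drop=True),
                       provenance=prov)

    # -- validation --------------------------------------------------------
    def range_violations(self) -> list[tuple]:
        """(row index, instrument, wave, value) for present out-of-range scores.

        Violations are reported, never clipped.  Continuous synthetic data is
        exempt by construction.
        """
        if self.continuous:
            return []
        out = []
        for spec in self.schema:
            for wave in WAVES:
                col = f"{spec.name}_{wave}"
                if col not in self.data.columns:
                    continue
                vals = self.data[col]
                bad = vals.notna() & ((vals < spec.score_min) | (vals > spec.score_max))
                for idx in self.data.index[bad]:
                    out.append((int(idx), spec.name, wave, float(vals[idx])))
        return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_trial_table(
    path,
    schema: tuple = DEFAULT_SCHEMA,
    missing_sentinels: tuple = ("", "NA"),
    continuous: bool = False,
) -> TrialDataset:
    """Read a wide-CSV trial table into a :class:`TrialDataset`.

    Score cells matching one of ``missing_sentinels`` become NaN.  Unknown
    arm labels raise :class:`SchemaError`; duplicated ids raise
    :class:`IntegrityError`.  Out-of-range present scores do not raise —
    inspect :meth:`TrialDataset.range_violations`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"id": str, "arm": str}, keep_default_na=False,
                     na_values=[], float_precision="round_trip")
    needed = {"id", "arm"}
    if missing := needed - set(df.columns):
        raise SchemaError(f"missing required column(s): {sorted(missing)}")
    for col in df.columns:
        if col in ("id", "arm"):
            continue
        if col in score_columns([s.name for s in schema]) or COVARIATES.get(col) == "numeric":
            ser = df[col].replace(list(missing_sentinels), np.nan)
            # float() parsing is exactly round-trip (pd.to_numeric is not).
            df[col] = ser.astype(float)
        else:
            df[col] = df[col].replace(list(missing_sentinels), np.nan)
    return TrialDataset(data=df, schema=schema, continuous=continuous,
                        provenance={"source": "observed", "path": str(path)})


def write_trial_table(ds: TrialDataset, path) -> Path:
    """Write the canonical wide CSV (empty cell = missing). Lossless for all
    cells: floats are serialized at round-trip precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # Shortest round-trip float representation keeps write -> read lossless.
    ds.data.to_csv(
        path, index=False, na_rep="",
        float_format=lambda v: np.format_float_positional(v, unique=True, trim="0"),
    )
    return path


# ---------------------------------------------------------------------------
# Results writing
# ---------------------------------------------------------------------------


def _round_floats(obj, ndigits: int):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _render_text(report: dict) -> str:
    """Human-readable rendering: estimates at 2 decimals, fit indices at 3."""
    lines = []
    meta = report.get("meta", {})
    if meta:
        lines.append("# " + ", ".join(f"{k}={v}" for k, v in sorted(meta.items())))
    for model in report.get("models", []):
        fs = model.get("fit_stats", {})
        lines.append(f"\n== model {model.get('model', '?')} ==")
        if fs:
            lines.append(
                "chi2={chi2:.1f} df={df} p={p:.3f} CFI={cfi:.3f} "
                "RMSEA={rmsea:.3f} [{lo:.3f}, {hi:.3f}] close-fit p={pc:.3f} "
                "SRMR={srmr:.3f}".format(
                    chi2=fs.get("chi2", float("nan")),
                    df=fs.get("df", 0),
                    p=fs.get("p", float("nan")),
                    cfi=fs.get("cfi", float("nan")),
                    rmsea=fs.get("rmsea", float("nan")),
                    lo=fs.get("rmsea_ci90", [float("nan")] * 2)[0],
                    hi=fs.get("rmsea_ci90", [float("nan")] * 2)[1],
                    pc=fs.get("rmsea_close_p", float("nan")),
                    srmr=fs.get("srmr", float("nan")),
                )
            )
        for par in model.get("parameters", []):
            se = par.get("se")
            se_txt = "" if se is None else f" ({se:.2f})"
            p = par.get("p")
            p_txt = "" if p is None else f" p={p:.3f}"
            lines.append(f"  {par['name']:<40s} {par['estimate']:8.2f}{se_txt}{p_txt}")
    for cmp_ in report.get("comparisons", []):
        lines.append(
            "\ncomparison {a} vs {b}: dchi2={d:.1f} ddf={ddf} p={p:.4g}".format(
                a=cmp_.get("nested"), b=cmp_.get("general"),
                d=cmp_.get("delta_chi2", float("nan")),
                ddf=cmp_.get("delta_df"), p=cmp_.get("p", float("nan")),
            )
        )
    return "\n".join(lines) + "\n"


def write_results(report: dict, path) -> Path:
    """Write an analysis report: JSON at ``path`` (full precision) and an
    aligned-text rendering alongside it (``.txt``).

    Serialization is idempotent: writing, reading and re-writing produces a
    byte-identical JSON file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
    path.write_text(payload + "\n")
    path.with_suffix(".txt").write_text(_render_text(report))
    return path


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())
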