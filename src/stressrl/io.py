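"""CSV schemas and round-trip readers/writers for pipeline artifacts.

All artifacts are plain CSV so runs stay auditable: trial logs, subject
manifests and fit tables. Headers are validated strictly — missing required
columns are errors, unknown columns a warning — and trial indices are
1-based throughout.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Subject
from .models import MODEL_FREE_PARAMS, AgentParams
from .task import InputError, TrialRecord

TRIAL_COLUMNS = [
    "subject_id",
    "trial",
    "block",
    "high_prob_option",
    "mag_A",
    "mag_B",
    "chosen",
    "rewarded",
    "response_made",
]

SUBJECT_COLUMNS = ["subject_id", "sex", "pss", "stress_group"]

FIT_COLUMNS = ["subject_id", "model", "log_lik", "log_post", "log_evidence",
               "hessian_ok", "n_restarts"]

NO_RESPONSE = ""  # empty cell marks a no-response trial


def _check_header(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    unknown = [c for c in frame.columns if c not in required]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=3)


def write_trials(trials_by_subject: dict[str, Sequence[TrialRecord]], path) -> None:
    """Write trial logs for any number of subjects to one CSV."""
    rows = []
    for sid, trials in trials_by_subject.items():
        for rec in trials:
            rows.append(
                {
                    "subject_id": sid,
                    "trial": rec.trial_index,
                    "block": rec.block_index,
                    "high_prob_option": rec.high_prob_option,
                    "mag_A": rec.magnitude_A,
                    "mag_B": rec.magnitude_B,
                    "chosen": rec.chosen if rec.chosen is not None else NO_RESPONSE,
                    "rewarded": rec.rewarded,
                    "response_made": int(rec.response_made),
                }
            )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_trials(path) -> dict[str, list[TrialRecord]]:
    """Read trial logs back into per-subject record lists."""
    frame = pd.read_csv(path, dtype={"chosen": "string", "rewarded": "string"})
    if frame.empty:
        warnings.warn(f"{path}: empty trial file", stacklevel=2)
        return {}
    _check_header(frame, TRIAL_COLUMNS, path)
    out: dict[str, list[TrialRecord]] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        chosen = None if pd.isna(row.chosen) or row.chosen == "" else str(row.chosen)
        if chosen not in (None, "A", "B"):
            raise InputError(f"{path}: row {i}: invalid chosen value {chosen!r}")
        if str(row.rewarded) not in ("A", "B"):
            raise InputError(f"{path}: row {i}: invalid rewarded value {row.rewarded!r}")
        rec = TrialRecord(
            trial_index=int(row.trial),
            block_index=int(row.block),
            high_prob_option=str(row.high_prob_option),
            magnitude_A=int(row.mag_A),
            magnitude_B=int(row.mag_B),
            rewarded=str(row.rewarded),
            chosen=chosen,
            response_made=bool(int(row.response_made)),
        )
        out.setdefault(str(row.subject_id), []).append(rec)
    for sid in out:
        out[sid].sort(key=lambda r: r.trial_index)
    return out


def write_subjects(subjects: Sequence[Subject], path) -> None:
    """Write the cohort manifest (metadata + true parameters if present)."""
    from .cohort import cohort_to_frame

    cohort_to_frame(list(subjects)).to_csv(path, index=False)


def read_subjects(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if frame.empty:
        warnings.warn(f"{path}: empty subject file", stacklevel=2)
        return frame
    missing = [c for c in SUBJECT_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return frame


def assemble_subjects(
    manifest: pd.DataFrame,
    trials_by_subject: dict[str, list[TrialRecord]],
    model_name: Optional[str] = None,
) -> list[Subject]:
    """Join a subject manifest with trial logs into Subject objects.

    ``true_*`` columns, when present and complete for ``model_name``,
    are reattached as generative parameters.
    """
    subjects = []
    for row in manifest.itertuples(index=False):
        sid = str(row.subject_id)
        params = None
        if model_name is not None:
            values = {}
            for name in MODEL_FREE_PARAMS[model_name]:
                col = f"true_{name}"
                if hasattr(row, col) and not pd.isna(getattr(row, col)):
                    values[name] = float(getattr(row, col))
            if len(values) == len(MODEL_FREE_PARAMS[model_name]):
                params = AgentParams(model_name, **values)
        subjects.append(
            Subject(
                subject_id=sid,
                sex=str(row.sex),
                pss=int(row.pss),
                generative_params=params,
                trials=trials_by_subject.get(sid, []),
            )
        )
    return subjects


def write_fits(fits_frame: pd.DataFrame, path) -> None:
    fits_frame.to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if frame.empty:
        warnings.warn(f"{path}: empty fits file", stacklevel=2)
        return frame
    missing = [c for c in FIT_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return frame


def fitted_param_table(fits: pd.DataFrame, model: str) -> pd.DataFrame:
    """Extract one model's fitted parameters, one row per subject."""
    cols = ["subject_id", *[c for c in MODEL_FREE_PARAMS[model] if c in fits.columns]]
    return fits.loc[fits.model == model, cols].reset_index(drop=True)
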