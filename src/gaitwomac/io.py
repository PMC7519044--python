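"""CSV schemas and the flat key-value configuration format.

Waveform CSV (long): subject_id, parameter, cycle_pct, value — 101 rows per
(subject, parameter) at integer cycle percents 0..100.
Spatiotemporal CSV: subject_id, name, value.
WOMAC CSV: subject_id, item_01..item_24 (derived columns such as totals and
classes are written by the pipeline, never read as input).
Phase CSV (optional): subject_id, toe_off_pct.

The config file is flat ``key = value`` text (``#`` comments allowed); keys
mirror :class:`PipelineConfig` and round-trip losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .cycle import GaitTrial, GaitWaveform, N_CYCLE_POINTS, default_phase_map
from .errors import ValidationError
from .registry import WAVEFORM_PARAMETERS
from .simulate import SyntheticSubject
from .womac import N_ITEMS, WOMACRecord, score_womac

logger = logging.getLogger(__name__)

_ITEM_COLUMNS = [f"item_{i:02d}" for i in range(1, N_ITEMS + 1)]


@dataclass
class PipelineConfig:
    """All pipeline knobs; every stochastic stage has an explicit seed."""

    out_dir: str = "gaitwomac_out"
    waveform_csv: str = ""
    spatiotemporal_csv: str = ""
    womac_csv: str = ""
    registry: str = "full"  # 'full' or 'key'
    alpha_anova: float = 0.0001
    alpha_pairwise: float = 0.00003
    balance_target: int = 231
    train_fraction: float = 0.70
    toe_off_pct: float = 60.0
    occupied_fraction: float = 0.99
    dtw_cost: str = "abs"
    linear_max_features: int = 20
    simulate: bool = False
    effect_scale: float = 1.0
    noise_scale: float = 1.0
    n_mild: int = 140
    n_moderate: int = 182
    n_severe: int = 53
    seed_cohort: int = 0
    seed_balance: int = 1
    seed_split: int = 2
    seed_forest: int = 3
    plots: bool = False

    def to_file(self, path) -> None:
        lines = [f"{f.name} = {getattr(self, f.name)}" for f in fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        values: Dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            values[key.strip()] = val.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name not in values:
                continue
            raw_val = values.pop(f.name)
            if f.type in ("int", int):
                kwargs[f.name] = int(raw_val)
            elif f.type in ("float", float):
                kwargs[f.name] = float(raw_val)
            elif f.type in ("bool", bool):
                kwargs[f.name] = raw_val.lower() in ("true", "1", "yes")
            else:
                kwargs[f.name] = raw_val
        if values:
            raise ValidationError(f"unknown config keys: {sorted(values)}")
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (paths excluded, so runs
        of the same analysis in different directories compare equal)."""
        import hashlib

        d = asdict(self)
        for key in ("out_dir", "waveform_csv", "spatiotemporal_csv", "womac_csv"):
            d.pop(key, None)
        return hashlib.sha256(repr(sorted(d.items())).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# writers


def write_cohort(subjects: Sequence[SyntheticSubject], out_dir) -> Dict[str, Path]:
    """Write the waveform / spatiotemporal / WOMAC CSVs for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials = [s.trial for s in subjects]
    records = [s.womac for s in subjects]
    paths = {
        "waveform_csv": out / "waveforms.csv",
        "spatiotemporal_csv": out / "spatiotemporal.csv",
        "womac_csv": out / "womac.csv",
    }
    write_trials(trials, paths["waveform_csv"], paths["spatiotemporal_csv"])
    write_womac(records, paths["womac_csv"])
    return paths


def write_trials(trials: Sequence[GaitTrial], waveform_csv, spatiotemporal_csv) -> None:
    wave_rows = []
    st_rows = []
    for t in trials:
        for param, wf in t.waveforms.items():
            wave_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": t.subject_id,
                        "parameter": param,
                        "cycle_pct": np.arange(N_CYCLE_POINTS),
                        "value": wf.values,
                    }
                )
            )
        for name, value in t.spatiotemporal.items():
            st_rows.append((t.subject_id, name, value))
    pd.concat(wave_rows, ignore_index=True).to_csv(waveform_csv, index=False)
    pd.DataFrame(st_rows, columns=["subject_id", "name", "value"]).to_csv(
        spatiotemporal_csv, index=False
    )


def write_womac(records: Sequence[WOMACRecord], womac_csv) -> None:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id}
        row.update({col: v for col, v in zip(_ITEM_COLUMNS, r.items)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(womac_csv, index=False)


# ---------------------------------------------------------------------------
# readers


def read_womac(womac_csv) -> List[WOMACRecord]:
    df = pd.read_csv(womac_csv)
    missing = [c for c in ["subject_id", *_ITEM_COLUMNS] if c not in df.columns]
    if missing:
        raise ValidationError(f"{womac_csv}: missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"{womac_csv}: duplicated subject_id {dupes[:5]}")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                score_womac([row[c] for c in _ITEM_COLUMNS], subject_id=str(row["subject_id"]))
            )
        except ValidationError as exc:
            raise ValidationError(f"{womac_csv}: subject {row['subject_id']}: {exc}") from None
    return records


def read_trials(
    waveform_csv, spatiotemporal_csv=None, phase_csv=None, toe_off_pct: float = 60.0
) -> List[GaitTrial]:
    df = pd.read_csv(waveform_csv)
    required = {"subject_id", "parameter", "cycle_pct", "value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{waveform_csv}: missing columns {sorted(required - set(df.columns))}")
    st: Dict[str, Dict[str, float]] = {}
    if spatiotemporal_csv is not None:
        st_df = pd.read_csv(spatiotemporal_csv)
        if not {"subject_id", "name", "value"}.issubset(st_df.columns):
            raise ValidationError(f"{spatiotemporal_csv}: expected subject_id,name,value")
        for _, row in st_df.iterrows():
            st.setdefault(str(row["subject_id"]), {})[str(row["name"])] = float(row["value"])
    toe_off: Dict[str, float] = {}
    if phase_csv is not None:
        ph = pd.read_csv(phase_csv)
        toe_off = dict(zip(ph["subject_id"].astype(str), ph["toe_off_pct"].astype(float)))

    trials = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sid = str(sid)
        waveforms = {}
        for param, block in sub.groupby("parameter"):
            block = block.sort_values("cycle_pct")
            pcts = block["cycle_pct"].to_numpy()
            expected = np.arange(N_CYCLE_POINTS)
            if pcts.shape[0] != N_CYCLE_POINTS or not np.array_equal(pcts, expected):
                absent = sorted(set(expected) - set(pcts.tolist()))
                raise ValidationError(
                    f"{waveform_csv}: subject {sid} parameter {param}: expected cycle "
                    f"positions 0..100, missing {absent[:10]}"
                )
            units = WAVEFORM_PARAMETERS.get(str(param), "")
            waveforms[str(param)] = GaitWaveform(str(param), block["value"].to_numpy(), units)
        pm = default_phase_map(toe_off.get(sid, toe_off_pct))
        trials.append(
            GaitTrial(
                subject_id=sid,
                waveforms=waveforms,
                spatiotemporal=st.get(sid, {}),
                phase_map=pm,
            )
        )
    return trials


def read_cohort(
    waveform_csv, spatiotemporal_csv, womac_csv, phase_csv=None, toe_off_pct: float = 60.0
) -> Tuple[List[GaitTrial], List[WOMACRecord]]:
    """Load trials and WOMAC records joined on subject_id; subjects missing
    either side are dropped with a logged count."""
    trials = read_trials(waveform_csv, spatiotemporal_csv, phase_csv, toe_off_pct)
    records = read_womac(womac_csv)
    trial_ids = {t.subject_id for t in trials}
    record_ids = {r.subject_id for r in records}
    common = trial_ids & record_ids
    dropped = (trial_ids | record_ids) - common
    if dropped:
        logger.warning("dropping %d subject(s) missing gait or WOMAC data", len(dropped))
    trials = [t for t in trials if t.subject_id in common]
    records = [r for r in records if r.subject_id in common]
    trials.sort(key=lambda t: t.subject_id)
    records.sort(key=lambda r: r.subject_id)
    return trials, records
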