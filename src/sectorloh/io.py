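"""Readers and writers for the pipeline's tab-separated file formats.

Formats (all plain text, tab-separated, headered unless noted):

* SNP map:      ``chrom  pos  name``           (1-based positions, sorted)
* ratio table:  ``chrom  pos  ratio_A  ratio_B``
* features BED: standard 0-based half-open BED, converted to 1-based
  inclusive on read (the only place coordinate conversion happens)
* event report: one row per classified event, TSV and JSON mirrors
* segments / transitions: TSV written by the segment command

Validation is strict: malformed rows raise with the file, line and field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ConversionEvent
from .enrichment import EnrichmentResult, FeatureTrack
from .segmentation import RatioProfile, Segment, TransitionInterval
from .snpmap import SnpMap

__all__ = [
    "read_snp_map",
    "write_snp_map",
    "read_ratio_table",
    "write_ratio_table",
    "read_features_bed",
    "write_features_bed",
    "write_event_report",
    "read_event_report",
    "write_segments",
    "write_enrichment",
]

_MAP_COLS = ["chrom", "pos", "name"]
_RATIO_COLS = ["chrom", "pos", "ratio_A", "ratio_B"]


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df


def read_snp_map(path) -> SnpMap:
    df = _read_tsv(path, _MAP_COLS)
    pos = df["pos"].to_numpy()
    if not np.issubdtype(pos.dtype, np.integer):
        raise ValueError(f"{path}: column 'pos' must be integer")
    if np.any(np.diff(pos) <= 0):
        bad = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 2
        raise ValueError(f"{path}: line {bad + 1}: positions not strictly increasing")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"{path}: expected a single chromosome, found {list(chroms)}")
    return SnpMap(
        chromosome=str(chroms[0]),
        positions=pos.astype(np.int64),
        names=tuple(df["name"].astype(str)),
    )


def write_snp_map(snp_map: SnpMap, path) -> None:
    pd.DataFrame(
        {
            "chrom": snp_map.chromosome,
            "pos": snp_map.positions,
            "name": list(snp_map.names),
        }
    ).to_csv(path, sep="\t", index=False)


def read_ratio_table(path, snp_map: SnpMap) -> RatioProfile:
    df = _read_tsv(path, _RATIO_COLS)
    if len(df) != len(snp_map):
        raise ValueError(
            f"{path}: {len(df)} rows but the SNP map has {len(snp_map)} markers"
        )
    if not np.array_equal(df["pos"].to_numpy(), snp_map.positions):
        raise ValueError(f"{path}: positions do not match the SNP map")
    for col in ("ratio_A", "ratio_B"):
        vals = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            bad = int(np.flatnonzero(~np.isfinite(vals) | (vals < 0))[0])
            raise ValueError(
                f"{path}: line {bad + 2}: field {col!r} must be finite and >= 0"
            )
    return RatioProfile(
        snp_map=snp_map,
        ratio_a=df["ratio_A"].to_numpy(dtype=float),
        ratio_b=df["ratio_B"].to_numpy(dtype=float),
    )


def write_ratio_table(profile: RatioProfile, path) -> None:
    pd.DataFrame(
        {
            "chrom": profile.snp_map.chromosome,
            "pos": profile.snp_map.positions,
            "ratio_A": profile.ratio_a,
            "ratio_B": profile.ratio_b,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_features_bed(path, name: str | None = None, midpoint_rule: bool = False) -> FeatureTrack:
    """Read a feature class from BED (0-based half-open -> 1-based inclusive)."""
    path = Path(path)
    intervals = []
    chroms = set()
    feature_name = name
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer start/end field"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start must be < end")
            chroms.add(fields[0])
            intervals.append((start + 1, end))
            if feature_name is None and len(fields) >= 4:
                feature_name = fields[3]
    if len(chroms) > 1:
        raise ValueError(f"{path}: feature tracks must be single-chromosome")
    return FeatureTrack(
        name=feature_name or path.stem,
        intervals=tuple(intervals),
        midpoint_rule=midpoint_rule,
        chromosome=chroms.pop() if chroms else "chrIV",
    )


def write_features_bed(track: FeatureTrack, path) -> None:
    with open(path, "w") as fh:
        for start, end in track.intervals:
            fh.write(f"{track.chromosome}\t{start - 1}\t{end}\t{track.name}\n")


def _transitions_str(transitions: list[TransitionInterval]) -> str:
    return ";".join(
        f"{t.left_pos}-{t.right_pos}:{t.left_state.value}>{t.right_state.value}"
        for t in transitions
    )


def _event_record(ev: ConversionEvent) -> dict:
    return {
        "event_id": ev.event_id,
        "class": ev.event_class,
        "timing": ev.timing,
        "donor": ev.donor if ev.donor is not None else "NA",
        "tract_min_bp": ev.tract.min_bp,
        "tract_max_bp": ev.tract.max_bp if ev.tract.max_bp is not None else "NA",
        "tract_avg_bp": ev.tract.avg_bp if ev.tract.avg_bp is not None else "NA",
        "open_ended": ev.tract.open_ended,
        "red_transitions": _transitions_str(ev.red_transitions),
        "white_transitions": _transitions_str(ev.white_transitions),
    }


def write_event_report(
    events: list[ConversionEvent], path, metadata: dict | None = None
) -> None:
    """Write the per-event report as TSV plus a JSON mirror (`<path>.json`)."""
    records = [_event_record(ev) for ev in events]
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
    payload = {"metadata": metadata or {}, "events": records}
    Path(str(path) + ".json").write_text(json.dumps(payload, indent=1))


def read_event_report(path) -> pd.DataFrame:
    return _read_tsv(
        path,
        ["event_id", "class", "timing", "donor", "tract_min_bp", "tract_max_bp"],
    )


def write_segments(
    segments: list[Segment],
    transitions: list[TransitionInterval],
    seg_path,
    trans_path,
) -> None:
    pd.DataFrame.from_records(
        [
            {
                "state": s.state.value,
                "first_index": s.first_index,
                "last_index": s.last_index,
                "first_pos": s.first_pos,
                "last_pos": s.last_pos,
            }
            for s in segments
        ]
    ).to_csv(seg_path, sep="\t", index=False)
    pd.DataFrame.from_records(
        [
            {
                "left_pos": t.left_pos,
                "right_pos": t.right_pos,
                "left_state": t.left_state.value,
                "right_state": t.right_state.value,
            }
            for t in transitions
        ]
    ).to_csv(trans_path, sep="\t", index=False)


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    pd.DataFrame.from_records(
        [
            {
                "feature_class": r.feature_class,
                "n_total": r.n_features_total,
                "window_fraction": r.window_fraction,
                "expected": r.expected,
                "observed": r.observed,
                "chi2": r.chi2,
                "p_value": r.p_value,
                "low_expected": r.low_expected,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
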