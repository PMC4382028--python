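#!/usr/bin/env python
"""Segment and classify the simulated sector pairs; tabulate the event
catalog the way a sectored-colony study reports it.

Reads results/sim/, runs the ratio -> zygosity -> segment -> combine ->
classify pipeline per sector pair, and writes the event report
(results/events.tsv + .json), the class/timing tallies, tract-length
medians by timing, and the per-SNP breakpoint-inclusion histogram.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from sectorloh import analyze_sector_pair, breakpoint_histogram, io

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
OUT = ROOT / "results"


def main() -> None:
    snp_map = io.read_snp_map(SIM / "snp_map.tsv")
    events = []
    for red_path in sorted(SIM.glob("event*_red.tsv")):
        white_path = SIM / red_path.name.replace("_red", "_white")
        events.append(
            analyze_sector_pair(
                io.read_ratio_table(red_path, snp_map),
                io.read_ratio_table(white_path, snp_map),
                event_id=red_path.stem.replace("_red", ""),
            )
        )
    io.write_event_report(events, OUT / "events.tsv", metadata={"n": len(events)})

    truth = json.loads((SIM / "truth.json").read_text())
    recovered = sum(
        ev.event_class == t["expected_class"] and ev.timing == t["expected_timing"]
        for ev, t in zip(events, truth)
    )
    df = pd.DataFrame(
        {
            "class": [ev.event_class for ev in events],
            "timing": [ev.timing for ev in events],
            "avg_bp": [ev.tract.avg_bp for ev in events],
        }
    )
    print(f"classified {len(events)} sector pairs; "
          f"{recovered}/{len(events)} match the simulated truth")
    print("class counts:", df["class"].value_counts().to_dict())
    print("timing counts:", df["timing"].value_counts().to_dict())
    with_tract = df.dropna(subset=["avg_bp"]).query("`class` != 'NO_GC'")
    med = with_tract.groupby("timing")["avg_bp"].median() / 1000
    print("median tract length (kb) by timing:", med.round(1).to_dict())

    hist = breakpoint_histogram(events, snp_map)
    pd.DataFrame(
        {"chrom": snp_map.chromosome, "pos": snp_map.positions, "count": hist}
    ).to_csv(OUT / "breakpoint_histogram.tsv", sep="\t", index=False)
    print(f"breakpoint histogram written; max inclusion count = {hist.max()}")


if __name__ == "__main__":
    main()
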