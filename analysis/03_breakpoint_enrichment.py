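#!/usr/bin/env python
"""Genome-element association at crossover breakpoints.

Builds crossover windows (last heterozygous SNP to first homozygous SNP)
for the classified events, then tests synthetic feature tracks: an
ARS-like track placed uniformly (expected: no enrichment), a track placed
preferentially inside windows (expected: enrichment), and a Ty-like track
of large elements scored by the midpoint rule.  Also reprints the
worked expectation for 28 features screened in 88 sectors.
"""

from pathlib import Path

import numpy as np

from sectorloh import (
    FeatureTrack,
    analyze_sector_pair,
    co_windows,
    expected_count,
    io,
    run_enrichment,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
REGION_BP = 1_100_000
SEED = 77


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
    windows = co_windows(events, snp_map)
    n_sectors = len(events)
    rng = np.random.default_rng(SEED)

    uniform = FeatureTrack(
        "uniform_ars_like",
        tuple(
            (int(s), int(s) + 200)
            for s in np.sort(rng.integers(1, REGION_BP - 200, size=28))
        ),
    )
    inside = []
    for w in rng.choice(windows, size=20):
        s = int(rng.integers(w.left, max(w.left + 1, w.right - 200)))
        inside.append((s, s + 200))
    enriched = FeatureTrack("window_seeking", tuple(sorted(inside)))
    ty_like = FeatureTrack(
        "ty_like_midpoint",
        tuple(
            (int(s), int(s) + 6_000)
            for s in np.sort(rng.integers(1, REGION_BP - 6_000, size=15))
        ),
        midpoint_rule=True,
    )

    results = [
        run_enrichment(track, windows, REGION_BP, n_sectors)
        for track in (uniform, enriched, ty_like)
    ]
    io.write_enrichment(results, ROOT / "results" / "enrichment.tsv")
    for r in results:
        print(
            f"{r.feature_class:>18}: f={r.window_fraction:.4f} "
            f"observed={r.observed} expected={r.expected:.1f} "
            f"chi2={r.chi2:.2f} p={r.p_value:.3g}"
        )
    print(
        "worked expectation (28 features, 88 sectors, f=2.12e-2):",
        round(expected_count(28, 88, 2.12e-2), 1),
    )


if __name__ == "__main__":
    main()
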