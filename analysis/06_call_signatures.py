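#!/usr/bin/env python
"""Duration/syllable trends and call-signature matching of fetal movements.

Tracks per-session median durations and syllable numbers of complete
orofacial units, then scores every session against the infant call-signature
boxes — contact (3.69-6.5 s, 5-9 syllables), twitter (0.96-1.5 s, 2-3), and
the bimodal lick union — with pregnancy-controlled regressions on the percent
match. Also reports the signature statistics of the infant call sample itself.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from fetalvoc.callclass import (
    DEFAULT_BOXES,
    box_capture,
    percent_match,
    type_likelihood,
)
from fetalvoc.events import unit_durations, unit_syllable_counts
from fetalvoc.readwrite import read_calls, read_sessions
from fetalvoc.trends import fit_polynomial, regress_with_pregnancy, select_poly_degree_aic


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sessions = read_sessions(args.data / "events.csv", args.data / "sessions.csv")
    calls = read_calls(args.data / "infant_calls.csv")

    rows = []
    for s in sessions:
        durs = unit_durations(s.orofacial_units, exclude_partial=True)
        sylls = unit_syllable_counts(s.orofacial_units, exclude_partial=True)
        if not durs:
            continue
        rows.append(
            {"session_id": s.session_id, "gestational_day": s.gestational_day,
             "median_duration_s": float(np.median(durs)),
             "q25_duration_s": float(np.percentile(durs, 25)),
             "q75_duration_s": float(np.percentile(durs, 75)),
             "median_syllables": float(np.median(sylls)),
             "q25_syllables": float(np.percentile(sylls, 25)),
             "q75_syllables": float(np.percentile(sylls, 75))}
        )
    trends = pd.DataFrame(rows)
    trends.to_csv(args.out / "duration_syllable_trends.csv", index=False)
    for col, label in (("median_duration_s", "duration"),
                       ("median_syllables", "syllable number")):
        degree = select_poly_degree_aic(trends["gestational_day"], trends[col])
        # the same degree is reused for the 25th/75th percentile curves
        fit = fit_polynomial(trends["gestational_day"], trends[col], degree)
        early, late = fit.predict(93), fit.predict(146)
        print(f"median {label}: AIC degree {degree}; "
              f"fitted E93 {early:.2f} -> E146 {late:.2f}")

    contact = [c for c in calls if c.type_label == "contact"]
    print(f"infant contact calls (n={len(contact)}): median duration "
          f"{np.median([c.duration_s for c in contact]):.2f} s, median "
          f"{np.median([c.syllable_count for c in contact]):.0f} syllables")

    days = np.array([s.gestational_day for s in sessions])
    pregs = np.array([s.pregnancy_id for s in sessions])
    match_rows = []
    for name, box in DEFAULT_BOXES.items():
        pm = np.array([percent_match(s, box) for s in sessions])
        finite = np.isfinite(pm)
        reg = regress_with_pregnancy(pm[finite], days[finite], pregs[finite])
        match_rows.extend(
            {"box": name, "session_id": s.session_id,
             "gestational_day": s.gestational_day, "pct_match": v}
            for s, v in zip(sessions, pm)
        )
        print(f"percent match {name}: beta±SE = {reg.slope:.3f}±{reg.se:.3f} "
              f"%/day, F[1,{reg.df_den}]={reg.f:.2f}, p={reg.p:.2g}")
    pd.DataFrame(match_rows).to_csv(args.out / "percent_match.csv", index=False)

    print(f"criteria checks on the infant sample: contact likelihood "
          f"{100*type_likelihood(calls, DEFAULT_BOXES['contact'], 'contact'):.0f}%, "
          f"twitter likelihood "
          f"{100*type_likelihood(calls, DEFAULT_BOXES['twitter'], 'twitter'):.0f}%, "
          f"lick capture "
          f"{100*box_capture(calls, DEFAULT_BOXES['lick'], 'lick'):.1f}%")


if __name__ == "__main__":
    main()
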