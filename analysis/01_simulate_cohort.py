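#!/usr/bin/env python
"""Generate the synthetic study cohort and write its raw tables.

Emulates the imaging design — four pregnancies scanned every few gestational
days from E93 to E146 — plus the infant call records and the mouth-opening
temporal profiles. Everything downstream (02-06) reads these files.
"""

import argparse
from pathlib import Path

from fetalvoc.pipeline import PipelineConfig
from fetalvoc.readwrite import (
    sessions_to_events,
    write_calls,
    write_events,
    write_profiles,
    write_session_meta,
    write_units,
)
from fetalvoc.synthetic import (
    CohortSpec,
    generate_cohort,
    generate_fetal_profiles,
    generate_infant_call_profiles,
    generate_infant_calls,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--pregnancies", type=int, default=4)
    parser.add_argument("--sessions", type=int, default=16)
    args = parser.parse_args()
    args.data.mkdir(parents=True, exist_ok=True)

    spec = CohortSpec(
        n_pregnancies=args.pregnancies, sessions_per_pregnancy=args.sessions
    )
    sessions = generate_cohort(spec, args.seed)
    write_events(sessions_to_events(sessions), args.data / "events.csv")
    write_session_meta(sessions, args.data / "sessions.csv")
    write_units(sessions, args.data / "units.csv")

    calls = generate_infant_calls(seed=args.seed)
    write_calls(calls, args.data / "infant_calls.csv")

    fetal = generate_fetal_profiles(sessions, seed=args.seed)
    write_profiles(fetal, args.data / "fetal_profiles")
    infant = generate_infant_call_profiles(seed=args.seed)
    write_profiles(infant, args.data / "infant_profiles")

    n_oro = sum(len(s.orofacial_units) for s in sessions)
    n_head = sum(len(s.head_units) for s in sessions)
    print(f"cohort: {len(sessions)} sessions across {args.pregnancies} pregnancies")
    print(f"movement units: {n_oro} orofacial, {n_head} head")
    print(f"infant calls: {len(calls)}; fetal profiles: {len(fetal)}; "
          f"infant profiles: {len(infant)}")
    print(f"written to {args.data}/")


if __name__ == "__main__":
    main()
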