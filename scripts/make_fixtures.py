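"""Regenerate the packaged fixture CSVs and truth sidecars.

Run from the repository root:  python scripts/make_fixtures.py
"""

from pathlib import Path

from chronuria.synth import PROFILES, generate
from chronuria.timeseries_io import write_series

DATA = Path(__file__).resolve().parents[1] / "src" / "chronuria" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    for profile, (truth, n) in PROFILES.items():
        series, truth_out = generate(truth, n, subject_id=profile)
        write_series(series, DATA / f"{profile}.csv")
        truth_out.to_json(DATA / f"{profile}.truth.json")
        print(f"{profile}: n={series.n} -> {DATA / (profile + '.csv')}")


if __name__ == "__main__":
    main()
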