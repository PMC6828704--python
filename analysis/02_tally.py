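"""Tally the simulated interactions by category, per session and overall.

Reads the dataset written by 01_simulate.py and writes the summary table to
results/tally.csv. The totals play the role of the study's headline counts
(hundreds of agonistic events, far fewer affiliative ones, concentrated among
the dominants).
"""

import sys
from pathlib import Path

import click

from dominet import read_interactions, tally_interactions

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "synthetic"


@click.command()
def main() -> None:
    records, sessions = read_interactions(
        DATA / "interactions.csv", DATA / "sessions.csv", DATA / "ethogram.yaml"
    )
    tally = tally_interactions(records, sessions)
    out = ROOT / "results" / "tally.csv"
    tally.to_csv(out)
    print(tally.to_string(float_format=lambda v: f"{v:.1f}"))
    total_ago = tally.loc["total", "agonistic"]
    total_aff = tally.loc["total", "affiliative"]
    print(f"\nTotal agonistic: {total_ago:.0f}  affiliative: {total_aff:.0f} -> {out}")


if __name__ == "__main__":
    sys.exit(main())
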