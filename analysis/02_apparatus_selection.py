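#!/usr/bin/env python
"""Rank the donor-compartment prototypes and report the selected design.

Loads the packaged table of the five glass donor-compartment prototypes,
recomputes the derived channel ratios (d_out/d_in and H_in/H_out, truncated
to two decimals as printed), applies the selection criteria — acute
inlet/outlet flow angle, widened base for eyeball coupling, largest
inlet/outlet height gap — and writes results/design_report.json.
"""

import json
from pathlib import Path

from lacriflow.geometry import design_report, load_table1

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    table = load_table1()
    report = design_report(table)
    (RESULTS / "design_report.json").write_text(json.dumps(report, indent=2) + "\n")
    for row in report["versions"]:
        print(f"version {row['version']}: d_out/d_in = {row['d_out/d_in']:.2f}, "
              f"H_in/H_out = {row['H_in/H_out']:.2f}, theta = {row['theta']}, "
              f"widened base = {row['widened_base']}")
    print(f"ranking: {report['ranking']}")
    print(f"selected donor compartment: version {report['selected_version']}")


if __name__ == "__main__":
    main()
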