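"""Validate the tuned model against the four canonical antennal-lobe computations.

Runs the 4-odor panel on the reference circuit at the standard sensitivity
multipliers (0.1, 0.04, 0.02, 0.4), scores firing-rate ranges, PN-vs-ORN
rate uniformity (Gini), odor-representation separation, and the ORN->PN
transfer exponent, then quantifies robustness with a Cohen's-d sensitivity
scan.  Writes results/validation_report.json and results/sensitivity.csv.
"""

import json
from pathlib import Path

from alsim.fixtures import (
    FIXTURE_SEED,
    fixture_circuit,
    fixture_door_matrix,
    fixture_protocol,
    fixture_spec,
    _assign_polarities,
)
from alsim.synthetic import generate_connectome
from alsim.validation import sensitivity_analysis, validate_circuit

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    weights, _ = fixture_circuit(FIXTURE_SEED)
    door = fixture_door_matrix(FIXTURE_SEED)
    protocol = fixture_protocol()

    report = validate_circuit(weights, door, protocol, seed=1)
    (OUT / "validation_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    print("canonical battery:")
    for k, v in report.checks.items():
        print(f"  {k:32s} {'PASS' if v else 'FAIL'}")
    print(f"  PN Gini {report.pn_gini:.3f} < ORN Gini {report.orn_gini:.3f}; "
          f"separation {report.pn_separation:.3f} > {report.orn_separation:.3f}; "
          f"transfer exponent {report.transfer_exponent:.2f}")

    roster, counts, _ = generate_connectome(fixture_spec(), seed=FIXTURE_SEED)
    roster, counts = _assign_polarities(roster, counts, FIXTURE_SEED)
    scan = sensitivity_analysis(
        roster, counts, door, protocol, scale_grid=(0.25, 0.5, 2.0, 4.0), n_multi=10, seed=1
    )
    scan.to_csv(OUT / "sensitivity.csv", index=False)
    print(f"sensitivity scan: {len(scan)} manipulations, "
          f"max |d| = {scan['cohens_d'].abs().max():.2f} -> sensitivity.csv")


if __name__ == "__main__":
    main()
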