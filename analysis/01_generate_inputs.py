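"""Generate every input the downstream analyses consume.

Writes the reference synthetic antennal-lobe connectome (roster, edge list,
glomerular volumes), the complete 8x4 odor-response matrix used for panel
simulations, and a DoOR-style matrix with 40% missingness together with its
alternating-least-squares completion, under results/inputs/.
"""

import json
from pathlib import Path

import numpy as np

from alsim.fixtures import (
    FIXTURE_SEED,
    fixture_door_matrix,
    fixture_spec,
    _assign_polarities,
)
from alsim.odor_drive import impute_missing_responses
from alsim.synthetic import generate_connectome, generate_door_matrix, write_connectome

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    roster, counts, volumes = generate_connectome(fixture_spec(), seed=FIXTURE_SEED)
    roster, counts = _assign_polarities(roster, counts, FIXTURE_SEED)
    paths = write_connectome(roster, counts, volumes, OUT / "connectome")
    print(f"connectome: {len(roster)} neurons ({roster.class_counts()}), "
          f"{int((counts > 0).sum())} edges -> {paths['roster'].parent}")

    door = fixture_door_matrix(FIXTURE_SEED)
    door.to_csv(OUT / "door_matrix.csv")
    print(f"odor panel: {door.shape[0]} glomeruli x {door.shape[1]} odors -> door_matrix.csv")

    # a larger DoOR-style matrix in the empirical missingness regime
    sparse = generate_door_matrix(20, 15, missing_fraction=0.4, seed=FIXTURE_SEED)
    sparse.to_csv(OUT / "door_sparse.csv")
    filled = impute_missing_responses(sparse, n_repeats=200, seed=FIXTURE_SEED)
    filled.to_csv(OUT / "door_imputed.csv")
    frac = float(sparse.isna().to_numpy().mean())
    print(f"sparse DoOR-style matrix: {frac:.0%} missing; ALS-imputed copy written "
          f"(all values in [{filled.min().min():.3f}, {filled.max().max():.3f}])")

    meta = {
        "seed": FIXTURE_SEED,
        "n_neurons": len(roster),
        "class_counts": roster.class_counts(),
        "missing_fraction": frac,
    }
    (OUT / "meta.json").write_text(json.dumps(meta, indent=2))


if __name__ == "__main__":
    main()
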