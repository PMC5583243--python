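#!/usr/bin/env python
"""Rotational correlation time from R2/R1 ratios, with and without
exclusion of exchange-broadened residues.

The destabilised dimer tumbles at ~15 ns; residues carrying R_ex bias the
estimate upward unless flagged and excluded."""

import json
from pathlib import Path

from vldyn.fast_relax import tauc_from_r2r1
from vldyn.synthetic import make_truth, simulate_relaxation_table

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    doc = {}
    for profile, tauc_true in (("LEN-like", 13.5), ("SMA-like", 15.0)):
        truth = make_truth(profile, seed=SEED, overrides={"tauc_true": tauc_true})
        table = simulate_relaxation_table(truth, field=600.0, noise_fraction=0.02,
                                          seed=SEED)
        flags = set(table[table.has_exchange].residue_id)
        excl = tauc_from_r2r1(table, field=600.0, rex_flags=flags)
        incl = tauc_from_r2r1(table, field=600.0)
        print(
            f"{profile:9s}: tauc = {excl.tauc:.1f} +/- {excl.sd:.1f} ns over "
            f"{excl.n_used} residues (truth {tauc_true} ns); without exchange "
            f"exclusion the estimate drifts to {incl.tauc:.1f} ns"
        )
        doc[profile] = {
            "tauc_true_ns": tauc_true,
            "tauc_ns": round(excl.tauc, 2),
            "sd_ns": round(excl.sd, 2),
            "n_used": excl.n_used,
            "tauc_unflagged_ns": round(incl.tauc, 2),
        }
    (OUT / "tumbling.json").write_text(json.dumps(doc, indent=1))
    print(f"wrote {OUT / 'tumbling.json'}")


if __name__ == "__main__":
    main()
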