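#!/usr/bin/env python
"""Amide chemical-shift perturbation mapping on a synthetic mutant.

Perturbations concentrate around the mutated site while the carbon
correlation stays >0.99 once the mutated residue is excluded — the
signature of a preserved backbone fold with a locally altered amide
environment."""

from pathlib import Path

from vldyn.chemshift import amide_csp, carbon_correlation, csp_to_frame
from vldyn.synthetic import make_truth, simulate_shift_tables

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = make_truth("quenched", seed=SEED)
    ref, mut = simulate_shift_tables(truth, mutated=("94",), seed=SEED)

    profile = amide_csp(ref, mut)
    csp_to_frame(profile).to_csv(OUT / "csp_profile.tsv", sep="\t", index=False)
    print(f"amide CSP over {len(profile.dd_amide)} residues: "
          f"{profile.mean:.2f} +/- {profile.sd:.2f} ppm")

    r2_excl, slope, intercept, n = carbon_correlation(ref, mut, "CA", exclude={"94"})
    r2_incl, *_ = carbon_correlation(ref, mut, "CA")
    print(f"13Ca correlation: R^2 = {r2_excl:.4f} over {n} residues "
          f"(mutated site excluded; {r2_incl:.4f} without exclusion)")
    print(f"wrote {OUT / 'csp_profile.tsv'}")


if __name__ == "__main__":
    main()
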