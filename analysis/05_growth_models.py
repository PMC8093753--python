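#!/usr/bin/env python
"""Model selection for temperature-adjusted maximum growth rate.

Fits nine nested-and-crossed OLS models (diameter, genome size, their
interaction, quadratic terms, habitat factor and combinations) on a common
complete-case row set, ranks them by AIC, and partitions the winning
model's R^2 into habitat and quadratic-diameter contributions. Also
quantifies how labelled oligotrophs and copiotrophs separate along each
trait dimension.
"""

import argparse
import json
from pathlib import Path

from microtraits import io
from microtraits.stats_suite import fit_model_suite, group_separation, variance_partition


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    species = io.read_species_table(args.outdir / "species_adjusted.csv")
    suite = fit_model_suite(species)
    io.write_table(suite.to_frame(), args.outdir / "model_suite.csv")
    print(suite.to_frame().round(3).to_string(index=False))
    print(f"\nbest model by AIC: {suite.best_label} (n = {suite.n})")

    part = variance_partition(suite)
    (args.outdir / "variance_partition.json").write_text(json.dumps(part, indent=2))
    print(f"variance partition: habitat {part['habitat_share']:.1%}, "
          f"nonlinear diameter {part['diameter_quadratic_share']:.1%}, "
          f"total {part['total']:.1%}")

    seps = {}
    for trait in ("g_adj", "cell_diameter_um", "genome_size_bp", "rrn_copies"):
        seps[trait] = group_separation(species, trait)
        print(f"oligotroph vs copiotroph on {trait}: "
              f"standardized difference {seps[trait]['standardized_mean_difference']:+.2f}")
    (args.outdir / "trophic_separation.json").write_text(json.dumps(seps, indent=2))


if __name__ == "__main__":
    main()
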