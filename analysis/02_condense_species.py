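#!/usr/bin/env python
"""Condense the record-level table to one row per species.

Averages quantitative traits (after robust outlier screening), applies
majority rule to categorical traits, and excludes intracellular species
and mycoplasmas, whose reduced genomes would otherwise distort the
genome-size dimension.
"""

import argparse
from pathlib import Path

from microtraits import io
from microtraits.condense import condense_records, filter_taxa


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = io.read_trait_table(args.outdir / "records.csv", strict=False)
    species = condense_records(records)
    n0 = len(species)
    species = filter_taxa(species, include_intracellular=False)
    io.write_table(species, args.outdir / "species.csv")

    print(f"{len(records)} records condensed to {n0} species")
    print(f"  excluded {n0 - len(species)} intracellular/mycoplasma species")
    print(f"  records per species: median "
          f"{species['n_records'].median():.0f}, max {species['n_records'].max()}")


if __name__ == "__main__":
    main()
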