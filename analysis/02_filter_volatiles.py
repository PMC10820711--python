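"""Apply the GC-MS peak-table quality filters.

Drops compounds whose maximum area never reaches 50,000 (irregular noise
peaks) and compounds not present in at least 80% of the readings of any
origin x roast replicate group (non-reproducible peaks), then reports what
was removed and writes the filtered table.
"""

import argparse
from pathlib import Path

from roastchem.containers import VolatileTable
from roastchem.gcms import abundance_filter, reproducibility_filter


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/filtered"))
    parser.add_argument("--abundance", type=float, default=50_000.0)
    parser.add_argument("--min-fraction", type=float, default=0.8)
    args = parser.parse_args()

    table = VolatileTable.read(args.data)
    filtered, dropped_low = abundance_filter(table, args.abundance)
    filtered, dropped_sporadic = reproducibility_filter(filtered, args.min_fraction)
    filtered.write(args.out)
    (args.out / "filter_log.txt").write_text(
        "# abundance filter\n" + "\n".join(dropped_low)
        + "\n# reproducibility filter\n" + "\n".join(dropped_sporadic) + "\n"
    )

    print(f"{table.n_compounds} compounds in, {filtered.n_compounds} retained")
    print(f"abundance filter (< {args.abundance:,.0f} max area): "
          f"{len(dropped_low)} dropped")
    print(f"reproducibility filter (< {args.min_fraction:.0%} of any group): "
          f"{len(dropped_sporadic)} dropped")


if __name__ == "__main__":
    main()
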