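#!/usr/bin/env python
"""Catalog tallies, chromosome grouping and a cross-species comparison.

Tallies the discovered catalog of the default bundle, recovers the
chromosome groups of the grouped bundle, and compares both against the
published-style per-family breakdown; writes tables under
results/catalog/.
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from silkatlas.catalog import (SpidroinCall, SpidroinCatalog, compare_catalogs,
                               tally_catalog)
from silkatlas.pipeline import catalog_from_discovery, discover, recover_groups
from silkatlas.synthetic import (load_terminal_library, paper_catalog_counts,
                                 read_bundle)

ROOT = pathlib.Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", default=ROOT / "results" / "bundle_default")
    ap.add_argument("--grouped", default=ROOT / "results" / "bundle_grouped")
    args = ap.parse_args()

    refs = load_terminal_library()
    outdir = ROOT / "results" / "catalog"
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = read_bundle(args.bundle)
    res = discover(bundle.proteome, refs)
    cat = catalog_from_discovery(res, species="synthetic-default")
    tal = tally_catalog(cat)
    print(f"[default] {tal['total']} spidroins "
          f"({tal['full_length']} full-length, {tal['partial']} partial): "
          f"{tal['by_type']}")

    gb = read_bundle(args.grouped)
    gres = discover(gb.proteome, refs)
    groups = recover_groups(gb, gres)
    rows = [{"chromosome": g.chromosome, "label": g.label,
             "size": len(g.members), "span": f"{g.span[0]}-{g.span[1]}",
             "members": ",".join(g.members)} for g in groups]
    pd.DataFrame(rows).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    print(f"[grouped] {len(groups)} chromosome groups: "
          + ", ".join(f"{g.chromosome}:{g.label} x{len(g.members)}"
                      for g in groups))

    published = SpidroinCatalog("orb-weaver-published", [
        SpidroinCall(gene_id=f"{t}{i}", sptype=t, confidence=1.0)
        for t, n in paper_catalog_counts().items() for i in range(n)])
    matrix = compare_catalogs([cat, catalog_from_discovery(gres, "synthetic-grouped"),
                               published])
    matrix.to_csv(outdir / "catalog_comparison.tsv", sep="\t")
    print("species x type matrix ->", outdir / "catalog_comparison.tsv")


if __name__ == "__main__":
    main()
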