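"""Optional integration checks against externally downloaded reference data.

These checks require two files that are NOT shipped with the package and
must be downloaded by the user:

* a yeast 3D genome model table (per-chromosome anchor points with bp and
  x, y, z columns; pass a dialect via --model-columns if the layout
  differs from chromosome/position/x/y/z),
* a YEASTRACT-style regulon table (TSV with tf/target/evidence columns),
* a yeast feature annotation (GFF3).

With those inputs this script reports the binding-evidence filter counts
(TFs / distinct targets / associations) and the top modules by KS
statistic, in the same format as the package's batch results.

Usage:
    python scripts/external_checks.py --model duan_model.tsv \
        --features saccharomyces_cerevisiae.gff3 --regulons yeastract.tsv
"""

from __future__ import annotations

import argparse

from coloc3d import (ModelDialect, batch_test, filter_regulons_by_evidence,
                     map_features, pairwise_distances, read_features,
                     read_model3d, read_regulons)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--model", required=True)
    ap.add_argument("--features", required=True)
    ap.add_argument("--regulons", required=True)
    ap.add_argument("--feature-class", default=None,
                    help="GFF3 feature class filter (default: all records)")
    ap.add_argument("--model-columns", default=None,
                    help="comma-separated header names for "
                         "chromosome,position,x,y,z")
    ap.add_argument("--min-targets", type=int, default=2)
    ap.add_argument("--top", type=int, default=10)
    args = ap.parse_args()

    dialect = None
    if args.model_columns:
        names = tuple(args.model_columns.split(","))
        if len(names) != 5:
            ap.error("--model-columns needs exactly 5 names")
        dialect = ModelDialect(names=names)

    model = read_model3d(args.model, dialect=dialect)
    print(f"model: {model.n_anchors} anchor points, "
          f"{len(model.chromosomes)} chromosomes")

    features = read_features(args.features, format="gff3",
                             feature_class=args.feature_class)
    print(f"features: {len(features)} records")

    regulons = read_regulons(args.regulons)
    binding = filter_regulons_by_evidence(regulons, {"binding"})
    print("binding-evidence filter:", binding.report)

    coords = map_features(model, features)
    print(f"mapped: {coords.n} features "
          f"({len(coords.report['skipped_chromosome_missing'])} skipped)")
    dset = pairwise_distances(coords)
    print(f"distances: {len(dset)} pairs")

    table, report = batch_test(dset, binding, min_targets=args.min_targets)
    print(f"m = {report['m']} modules tested; top {args.top} by KS D:")
    print(table.head(args.top).to_string(index=False))


if __name__ == "__main__":
    main()
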