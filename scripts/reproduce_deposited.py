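#!/usr/bin/env python
"""Run the full benchmark on locally downloaded deposited datasets.

The curated antifreeze-protein FASTA datasets are deposited at
https://github.com/ryomiya/Prediction-and-analysis-of-antifreeze-proteins.
This script performs no network access: download the positive and
negative FASTA files yourself, then run e.g.

    python scripts/reproduce_deposited.py \
        --pos dataset_S.fasta --neg negatives.fasta \
        --seed 1 --out-dir results/dataset_S

It reads both files, samples a balanced negative set, extracts the
988-dimensional descriptors, runs five-fold cross-validation and an
independent 64/16/20 test, and writes metric tables plus the top-10
importance table.  Retrained accuracies are stochastic and depend on
the exact deposited snapshot; expect values close to, but not equal to,
any previously published numbers.
"""

from __future__ import annotations

import argparse
from pathlib import Path

from afpkit import datasets as D
from afpkit import metrics as X
from afpkit import model as M
from afpkit import seqio

METRIC_HEADER = "\t".join(X.MetricsReport.SCALAR_FIELDS)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pos", type=Path, required=True,
                        help="positive (AFP) FASTA file")
    parser.add_argument("--neg", type=Path, required=True,
                        help="negative (non-AFP) FASTA pool")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--folds", type=int, default=5)
    parser.add_argument("--out-dir", type=Path, default=Path("deposited_run"))
    args = parser.parse_args()

    positives = seqio.read_fasta(args.pos, label=seqio.POSITIVE)
    pool = seqio.read_fasta(args.neg, label=seqio.NEGATIVE)
    negatives = D.sample_balanced_negatives(pool, len(positives), seed=args.seed)
    ds = D.LabeledDataset.from_records(
        positives + negatives,
        provenance=f"deposited pos={args.pos} neg={args.neg} seed={args.seed}")

    args.out_dir.mkdir(parents=True, exist_ok=True)

    fold_reports, cv_mean = M.cross_validate(ds, k=args.folds, seed=args.seed)
    with open(args.out_dir / "cv_metrics.tsv", "w") as fh:
        fh.write("fold\t" + METRIC_HEADER + "\n")
        for i, rep in enumerate(fold_reports, start=1):
            fh.write(f"{i}\t{rep.tsv_row()}\n")
        fh.write(f"mean\t{cv_mean.tsv_row()}\n")
    cv_mean.roc_csv(args.out_dir / "cv_pooled_roc.csv")

    train_ds, valid_ds, test_ds = D.split_train_valid_test(ds, seed=args.seed)
    fitted = M.train(train_ds, valid_ds, seed=args.seed)
    report = X.evaluate(test_ds.labels,
                        M.predict_proba(fitted, test_ds.extract_features()))
    with open(args.out_dir / "independent_test_metrics.tsv", "w") as fh:
        fh.write(METRIC_HEADER + "\n" + report.tsv_row() + "\n")

    M.feature_importance(M.train(ds, seed=args.seed)).to_tsv(
        args.out_dir / "importance_top10.tsv", top=10)

    print(f"CV mean:\n{METRIC_HEADER}\n{cv_mean.tsv_row()}")
    print(f"Independent test:\n{METRIC_HEADER}\n{report.tsv_row()}")
    print(f"outputs in {args.out_dir}")


if __name__ == "__main__":
    main()
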