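#!/usr/bin/env python
"""Optional full-protocol learning curve on an externally supplied corpus.

The incremental-annotation evaluation on the real BioNLP-NLPBA 2004 corpus
requires that corpus to be downloaded separately (it is not bundled and is
never fetched by this script).  Given local token-per-line IOB files it
trains on growing prefixes of the training file and evaluates every model
on the fixed development file:

    python scripts/run_nlpba_curve.py --train Genia4ERtask1.iob2 \
        --dev Genia4EReval1.iob2 --schedule 40,120,280,600 --out curve.tsv

Absolute scores depend on the engine and feature models used, so numbers
from this script are comparable in curve shape, not in absolute value, to
previously published runs.
"""

import argparse
import sys
from pathlib import Path


def main(argv=None):
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--train", required=True, help="IOB training corpus")
    ap.add_argument("--dev", required=True, help="IOB development corpus")
    ap.add_argument("--schedule", default="40,120,280,600,1240,2520,5080,10200,18555")
    ap.add_argument("--epochs", type=int, default=5)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="curve.tsv")
    args = ap.parse_args(argv)

    for path in (args.train, args.dev):
        if not Path(path).exists():
            print(f"error: corpus file not found: {path}\n"
                  f"This protocol needs a locally downloaded corpus; "
                  f"nothing is fetched automatically.", file=sys.stderr)
            return 1

    from looptag import read_iob
    from looptag.simulate import curve_tsv, run_learning_curve

    with open(args.train, encoding="utf-8") as fh:
        corpus = read_iob(fh)
    with open(args.dev, encoding="utf-8") as fh:
        dev = read_iob(fh)
    schedule = [int(x) for x in args.schedule.split(",") if x.strip()]
    n = sum(len(d.sentences) for d in corpus)
    schedule = [s for s in schedule if s <= n] or [n]
    points = run_learning_curve(corpus, dev, schedule,
                                epochs=args.epochs, seed=args.seed)
    Path(args.out).write_text(curve_tsv(points), encoding="utf-8")
    print(curve_tsv(points), end="")
    return 0


if __name__ == "__main__":
    sys.exit(main())
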