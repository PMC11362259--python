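"""Re-run the morph pipeline on the deposited chimpanzee field data.

The published dataset-dependent results (7879 tokens, 61 -> 42 actions,
527 combinations, 115 morphs, naive Bayes accuracies, entropy counts)
require the field data deposited in the study's public repository, which
this package does not bundle. Download the token table separately, then:

    python scripts/external_validation.py --tokens <path-to-tokens.csv> \
        --out results/external/

The script runs the full pipeline at field thresholds and prints the
headline counts next to nothing else; comparison with the published
values is left to the reader.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import gesturemorphs as gm  # noqa: E402
from gesturemorphs.io import default_table_path  # noqa: E402


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--tokens", type=Path, default=None,
                    help="token table CSV exported from the deposited data")
    ap.add_argument("--schema", type=Path, default=None)
    ap.add_argument("--out", type=Path, default=Path("results/external"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args(argv)

    if args.tokens is None or not args.tokens.exists():
        print(
            "No token table given (or file not found).\n"
            "This validation needs the deposited field data, which must be\n"
            "downloaded separately; pass its token CSV via --tokens.",
            file=sys.stderr,
        )
        return 2

    schema = gm.schema_from_yaml(
        args.schema or default_table_path("chimp_schema.yaml"))
    table = gm.read_tokens(args.tokens, schema)
    config = gm.RunConfig(out_dir=str(args.out), master_seed=args.seed)
    result = gm.run_pipeline(table, config)
    s = result.summary
    print(f"tokens read:            {len(table)}")
    print(f"tokens preprocessed:    {result.n_tokens_preprocessed}")
    print(f"tokens assignable:      {result.n_tokens_assignable}")
    print(f"actions analysed:       {s['n_actions']}")
    print(f"total morphs:           {s['total_morphs']}")
    print(f"single-morph actions:   {s['single_morph_actions']}")
    print(f"unexplained morphs:     {s['n_unexplained']}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
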