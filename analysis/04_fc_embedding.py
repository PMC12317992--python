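"""Two-task functional-connectivity embedding before and after separation.

Simulates individuals performing two overlapping tasks, builds each
individual's task FC from their trial windows, embeds all FCs with UMAP and
classifies them with an RBF SVM — once on the raw windows and once after
Active-Cortex-Model separation.  Separation should tighten task clusters and
raise classification accuracy.
"""

import argparse
import json
from pathlib import Path

from activecortex.studies import two_task_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--replicates", type=int, default=3)
    parser.add_argument("--out", default="results")
    args = parser.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    res = two_task_study(seed=args.seed, n_replicates=args.replicates)
    (out / "fc_embedding.json").write_text(json.dumps(res, indent=1))
    print(
        "embedded-space SVM accuracy: "
        f"unseparated {res['median_svm_accuracy_unseparated']:.2f} -> "
        f"ACM {res['median_svm_accuracy_acm']:.2f}"
    )
    print(
        "between/within cluster distance ratio: "
        f"unseparated {res['median_distance_ratio_unseparated']:.2f} -> "
        f"ACM {res['median_distance_ratio_acm']:.2f}"
    )


if __name__ == "__main__":
    main()
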