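#!/usr/bin/env python
"""Diagnostic accuracy of the qualitative perfusion reads.

Evaluates the benchmark 2x2 table of reader-based perfusion calls
(decreased vs normal uptake) against follow-up outcome: 5 TP, 6 FP, 1 FN,
18 TN over 30 patients.  Prints sensitivity, specificity, accuracy, and
the likelihood ratios with log-method 95% CIs; writes the JSON report.
"""

import json
from pathlib import Path

from hipspect import ContingencyTable, evaluate_table

OUT = Path(__file__).resolve().parents[1] / "results"

READER_TABLE = ContingencyTable(tp=5, fp=6, fn=1, tn=18)


def main():
    OUT.mkdir(exist_ok=True)
    s = evaluate_table(READER_TABLE, alpha=0.05)
    print(f"2x2 table: TP={READER_TABLE.tp} FP={READER_TABLE.fp} "
          f"FN={READER_TABLE.fn} TN={READER_TABLE.tn} (n={READER_TABLE.total})")
    print(f"sensitivity {100 * s.sensitivity:.1f}%  "
          f"specificity {100 * s.specificity:.1f}%  "
          f"accuracy {100 * s.accuracy:.1f}%")
    print(f"LR+ {s.lr_pos:.2f} (95% CI {s.ci_lr_pos[0]:.2f}-{s.ci_lr_pos[1]:.2f})")
    print(f"LR- {s.lr_neg:.2f} (95% CI {s.ci_lr_neg[0]:.2f}-{s.ci_lr_neg[1]:.2f})")

    payload = {
        "table": {"tp": READER_TABLE.tp, "fp": READER_TABLE.fp,
                  "fn": READER_TABLE.fn, "tn": READER_TABLE.tn},
        "sensitivity": s.sensitivity,
        "specificity": s.specificity,
        "accuracy": s.accuracy,
        "lr_pos": s.lr_pos,
        "ci_lr_pos": list(s.ci_lr_pos),
        "lr_neg": s.lr_neg,
        "ci_lr_neg": list(s.ci_lr_neg),
        "alpha": s.alpha,
    }
    (OUT / "diagnostic_accuracy.json").write_text(json.dumps(payload, indent=2))
    print(f"wrote {OUT / 'diagnostic_accuracy.json'}")


if __name__ == "__main__":
    main()
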