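#!/usr/bin/env python
"""Assemble the cohort markdown report from the tables written by the
earlier steps; writes results/report.md."""

from pathlib import Path

from mtsig.report import build_report

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    text = build_report(ROOT)
    (ROOT / "report.md").write_text(text)
    print(text)
    print(f"wrote {ROOT / 'report.md'}")


if __name__ == "__main__":
    main()
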