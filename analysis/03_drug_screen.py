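#!/usr/bin/env python
"""Normalize plate RLUs, apply QC, call hits, and summarize drug classes.

Cytotoxicity = 100*(1 - RLU/median DMSO RLU) per plate; a plate passes QC if
staurosporine kill >= 80% and DMSO CV <= 0.2; a drug is a hit if its mean
cytotoxicity across QC-passing samples exceeds 33%.
"""

from pathlib import Path

from nbscreen import pipeline_io as io

from _shared import OUT, run_config


def main() -> None:
    io.configure_logging()
    cfg = run_config()
    data = io.ingest_stage(OUT / "cohort")
    data = io.screen_stage(cfg, data, OUT)
    c = data.counts
    means = data.cytotox.drug_means
    pct_positive = 100.0 * (means > 0).mean()
    pct_hits = 100.0 * c["n_hits"] / len(means)
    print(f"plates passing QC: {c['n_plates_qc_pass']}/{c['n_plates']}")
    print(f"{(means > 0).sum()} ({pct_positive:.1f}%) compounds with positive "
          f"mean cytotoxicity; {c['n_hits']} ({pct_hits:.1f}%) hits above 33%")
    top = means.sort_values(ascending=False).head(5)
    names = data.drug_library.set_index("compound_id")["name"]
    for cid, m in top.items():
        print(f"  top hit {names.get(cid, cid)}: {m:.1f}%")


if __name__ == "__main__":
    main()
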