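#!/usr/bin/env python
"""Library- and gene-level quality control.

Thresholds are the synthetic-scale analogues of the standard filters
(aligned-read and detected-gene minima, genes detected in >= 3 nuclei): the
simulated libraries carry ~2000 transcript counts (~200,000 emulated
aligned reads) and detect ~700 of 2000 genes, so the detected-gene floor is
set to 300. Writes the filtered matrix and a QC report under results/qc/.
"""

from pathlib import Path

from embryoatlas.ingest import (filter_genes_min_nuclei, qc_filter_nuclei,
                                read_expression, write_expression)

ROOT = Path(__file__).resolve().parents[1] / "results"

MIN_READS = 100_000
MIN_GENES = 300
MIN_NUCLEI = 3


def main() -> None:
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    m = read_expression(ROOT / "data" / "counts.mtx", fmt="mtx",
                        nucleus_meta=ROOT / "data" / "counts.nucleus_meta.tsv",
                        gene_meta=ROOT / "data" / "counts.gene_meta.tsv")
    m, report = qc_filter_nuclei(m, min_reads=MIN_READS, min_genes=MIN_GENES)
    m = filter_genes_min_nuclei(m, min_nuclei=MIN_NUCLEI, min_value=1)
    write_expression(m, out, fmt="mtx", prefix="qc")
    report.to_json(out / "qc_report.json")
    print(f"retained {report.n_retained}/{report.n_input} nuclei "
          f"({report.retention_pct_rounded:.0f}%); "
          f"{report.removed_low_reads} failed the read filter, "
          f"{report.removed_low_genes} the detected-gene filter")
    print(f"{m.n_genes} genes detected in >= {MIN_NUCLEI} nuclei")


if __name__ == "__main__":
    main()
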