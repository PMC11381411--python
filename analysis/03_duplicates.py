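"""Duplicate census at the five-difference threshold, checked against truth.

Calls duplicate clusters (single-linkage components of the <=5-difference
graph), writes the census table, and compares the called partition with the
planted ground truth from step 01.
"""

from pathlib import Path

import pandas as pd

from ssrdup.distances import pairwise_differences
from ssrdup.duplicates import (
    call_duplicates,
    census_table,
    render_census,
    write_census_csv,
)
from ssrdup.matrix import read_band_matrix, read_metadata

BASE = Path(__file__).resolve().parent.parent / "results"
THRESHOLD = 5


def main() -> None:
    matrix = read_band_matrix(BASE / "collection" / "matrix.csv")
    meta = read_metadata(BASE / "collection" / "metadata.csv")
    d = pairwise_differences(matrix)
    census = call_duplicates(d, threshold=THRESHOLD)

    write_census_csv(census, BASE / "census.csv", meta)
    table = census_table(census, meta)
    (BASE / "census.txt").write_text(render_census(table))

    truth = pd.read_csv(BASE / "collection" / "truth.csv").fillna("")
    planted = {
        frozenset(grp["accession_id"])
        for gid, grp in truth[truth["group_id"] != ""].groupby("group_id")
    }
    print(
        f"{len(census.clusters)} duplicate clusters at <= {THRESHOLD} differences; "
        f"{census.n_accessions_in_clusters} accessions in clusters, "
        f"{census.n_singletons} singletons, "
        f"{census.n_unique_genotypes} unique genotypes"
    )
    print(f"cluster sizes: {census.size_distribution}")
    print(f"called partition equals planted truth: {census.member_sets() == planted}")


if __name__ == "__main__":
    main()
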