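"""Rank a case's figures against a query by keypoint votes.

Indexes ten micrograph phantoms plus one horizontally mirrored copy,
then queries with the original: the mirrored copy must rank first,
which is what the mirror-augmented description is for.
"""

import numpy as np

from scifig.retrieval import build_index, query_rank
from scifig.synthetic import make_micrograph_panel
from scifig.types import FigureRecord, RasterImage

figures = [
    FigureRecord(id=f"fig{k}", image=make_micrograph_panel(100 + k, n_cells=12))
    for k in range(10)
]
mirrored = np.ascontiguousarray(figures[0].image.pixels[:, ::-1])
figures.append(FigureRecord(id="fig0-mirrored", image=RasterImage(mirrored, "m")))

index = build_index(figures, n_points=300)
rank = query_rank(index, figures[0], k_nn=8)

print(f"query: {figures[0].id}  (index holds {len(index)} descriptors)")
for fid, votes in rank.entries[:5]:
    print(f"  {fid:>14}: {votes} votes")
# Each of the query's descriptors votes for the figures owning its 8
# nearest stored descriptors.  The mirrored duplicate shares (mirrored)
# content with the query, so it collects far more votes than the
# unrelated micrographs and appears at rank 1.
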