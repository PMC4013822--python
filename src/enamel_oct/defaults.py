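"""Default pipeline constants.

Every method constant (acquisition geometry, filter sizes, search ranges)
lives in this table and only here; the rest of the package pulls keyword
defaults from these names so there is a single override point.
"""

#: Physical size of one axial pixel (depth direction), micrometres.
AXIAL_UM_PER_PX = 5.0
#: Physical size of one lateral pixel (column direction), micrometres.
LATERAL_UM_PER_PX = 11.7
#: Distance between consecutive B-scans, micrometres.
SLICE_UM = 47.0

#: 3-D median mask applied to the raw grey-level volume.
H1 = (3, 3, 3)
#: 3-D median mask applied to the binary volume.
H2 = (3, 3, 3)
#: In-plane structuring element for morphological closing.
SE = (3, 3)
#: 2-D median mask applied to the projection image before ROI delineation.
H3 = (31, 31)

#: Exhaustive registration search range for both shift axes, pixels.
SHIFT_RANGE_PX = 40
#: Zoom levels searched during registration, percent of the reference.
ZOOM_PERCENTS = (-20, -10, 0, 10, 20)

#: Maximum tolerated disagreement between the two inner-boundary threshold
#: candidates before a column is declared ambiguous (70 px = 350 um axially).
LIMIT_SHIFT_PX = 70
#: Number of neighbouring columns whose median replaces an ambiguous column.
NEIGHBOR_WINDOW = 5

#: Degree of the polynomial smoothing the raw inner boundary.
POLY_DEGREE = 3

#: Active-contour vertex search range along its ray per sweep, pixels.
CONTOUR_SEARCH_RANGE_PX = 20
#: Side of the square averaging patch sampled on both sides of a vertex.
CONTOUR_PATCH_PX = 6
#: Hard iteration cap for the active contour.
CONTOUR_MAX_ITERS = 200
#: Initial contour inset from the frame border, pixels.
CONTOUR_INIT_MARGIN_PX = 4
#: Number of contour vertices.
CONTOUR_VERTICES = 64

#: Treatment-stage labels, in acquisition order.
STAGE_LABELS = ("a", "b", "c", "d", "e", "f", "g")
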