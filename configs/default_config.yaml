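arcsinh_cofactor: 150.0
dapi_min: null
area_min: 10.0
area_max: 220.0
n_pcs: 20
knn_graph_k: 30
leiden_resolution: 2.0
interaction_radius: 20.0
interaction_knn: 3
window_k: 10
n_neighbourhoods: 10
margin_distance: 30.0
min_nest_area: 100.0
raster_pixel: 2.0
cell_stamp_radius: 5.0
closing_radius: 10.0
pseudofrequency: 0.001
annotation_floor: 0.2
seed: 0
markers:
- PanCK
- CD117
- Ki67
- CD45
- CD20
- CD3e
- CD4
- CD45RO
- CD45RA
- CD8
- CD107a
- CD44
- FoxP3
- CD25
- CD197
- CD11b
- CD14
- CD15
- CD68
- HLADR
- CD141
- CD31
- CD34
- Podoplanin
- Vimentin
signatures:
  B cell:
  - CD45
  - CD45RA
  - CD20
  Blood vessel:
  - CD31
  - CD34
  Lymphatic:
  - Podoplanin
  CD4 T cell:
  - CD45
  - CD3e
  - CD4
  - CD45RO
  CD8 T cell:
  - CD45
  - CD3e
  - CD8
  - CD45RO
  Granulocyte:
  - CD15
  - CD141
  - CD11b
  Lymphocyte:
  - CD45
  Vessel lymphocyte:
  - CD45
  - CD31
  Macrophage:
  - CD68
  - CD107a
  - CD14
  Mast cell:
  - CD117
  Monocyte:
  - CD14
  Proliferating lymphocyte:
  - CD45
  - Ki67
  Stroma:
  - Vimentin
  Treg:
  - CD45
  - CD4
  - FoxP3
  - CD25
  Effector CD4 T cell:
  - CD45
  - CD4
  - HLADR
  - CD197
  CCR7 CD8 T cell:
  - CD45
  - CD45RO
  - CD8
  - CD197
  Tumour HLADR:
  - PanCK
  - HLADR
  Tumour CD44:
  - PanCK
  - CD44
  Tumour Ki67:
  - PanCK
  - Ki67
tumour_types:
- Tumour HLADR
- Tumour CD44
- Tumour Ki67
excluded_cores: []
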