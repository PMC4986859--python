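((Calycanthus_occidentalis:1.0,Magnolia_salicifolia:1.0):1.0,(Hosta_fortunei:1.0,((Epimedium_versicolor:1.0,Helleborus_orientalis:1.0):1.0,(Sarcococca_hookeriana:1.0,((('Bergenia ''Abendglut''':1.0,(Paeonia_potaninii:1.0,Parrotiopsis_jacquemontiana:1.0):1.0):1.0,((Euonymus_hamiltonianus:1.0,((Viola_sororia:1.0,Populus_tremula:1.0):1.0,(Erythrina_crista-galli:1.0,(Ficus_carica:1.0,Fagus_sylvatica:1.0):1.0):1.0):1.0):1.0,(Eucalyptus_pauciflora:1.0,(Arabidopsis_thaliana:1.0,(Hibiscus_moscheutos:1.0,Skimmia_japonica:1.0):1.0):1.0):1.0):1.0):1.0,((Persicaria_amplexicaulis:1.0,(Talinum_paniculatum:1.0,(Amaranthus_hybridus:1.0,(Phytolacca_americana:1.0,Mirabilis_longiflora:1.0):1.0):1.0):1.0):1.0,(((Cornus_sanguinea:1.0,Cornus_stolonifera:1.0):1.0,Hydrangea_macrophylla:1.0):1.0,(((Arbutus_unedo:1.0,Rhododendron_catawbiense:1.0):1.0,(Camellia_japonica:1.0,Diospyros_virginiana:1.0):1.0):1.0,((Aucuba_japonica:1.0,Ipomoea_purpurea:1.0):1.0,(Ilex_aquifolium:1.0,(Hedera_helix:1.0,Menyanthes_trifoliata:1.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0):1.0);
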