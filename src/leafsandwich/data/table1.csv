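species,family,functional_group,E_T,E_B,ratio,thickness,alpha,E_f,E_c,EB_I
Amaranthus hybridus,Amaranthaceae,H/D,8.3,23.6,2.91,0.229,0.792,50,-2.6,0.023
Arabidopsis thaliana,Brassicaceae,H/D,2.4,4.9,2.04,0.206,0.802,11,0.8,0.004
Bergenia 'Abendglut',Saxifragaceae,H/D,8.3,23.2,2.82,0.426,0.848,62,-1.1,0.153
Hibiscus moscheutos,Malvaceae,H/D,9.3,14.2,1.58,0.268,0.813,25,6.0,0.026
Hosta fortunei,Asparagaceae,H/D,22.5,62.5,2.9,0.239,0.731,108,-9.3,0.072
Ipomoea purpurea,Convolvulaceae,H/D,4.8,17.5,3.58,0.196,0.781,39,-4.2,0.012
Menyanthes trifoliata,Menyanthaceae,H/D,6.6,19.3,2.96,0.285,0.851,53,-1.5,0.037
Mirabilis longiflora,Nyctaginaceae,H/D,4.4,11.4,2.57,0.351,0.841,28,-0.2,0.043
Paeonia potaninii,Paeoniaceae,H/D,11.7,37.3,3.19,0.431,0.887,131,-3.6,0.242
Persicaria amplexicaulis,Polygonaceae,H/D,5.8,15.4,2.71,0.243,0.705,25,-2.5,0.018
Phytolacca americana,Phytolaccaceae,H/D,7.2,20.0,2.8,0.232,0.846,53,-1.0,0.022
Talinum paniculatum,Talinaceae,H/D,2.8,7.3,2.65,0.973,0.923,36,0.2,0.581
Viola sororia,Violaceae,H/D,14.4,46.1,3.34,0.175,0.654,71,-14.3,0.020
Epimedium versicolor,Berberidaceae,H/E,52.7,151.4,2.87,0.177,0.808,338,-15.6,0.068
Helleborus orientalis,Ranunculaceae,H/E,54.6,158.1,2.91,0.304,0.8,345,-17.2,0.381
Calycanthus occidentalis,Calycanthaceae,W/D,24.9,61.3,2.47,0.26,0.839,149,1.3,0.090
Cornus sanguinea,Cornaceae,W/D,6.7,14.6,2.19,0.194,0.837,34,1.5,0.009
Cornus stolonifera,Cornaceae,W/D,10.5,19.9,1.85,0.185,0.842,43,4.5,0.012
Diospyros virginiana,Ebenaceae,W/D,20.3,57.9,2.86,0.252,0.849,157,-3.6,0.078
Erythrina crista-galli,Fabaceae,W/D,34.0,84.1,2.53,0.321,0.866,232,2.8,0.238
Euonymus hamiltonianus,Celastraceae,W/D,16.2,39.7,2.47,0.302,0.825,91,0.5,0.093
Fagus sylvatica,Fagaceae,W/D,56.2,141.5,2.57,0.159,0.852,368,2.2,0.048
Ficus carica,Moraceae,W/D,12.7,17.1,1.43,0.329,0.769,23,9.5,0.050
Hydrangea macrophylla,Hydrangeaceae,W/D,7.7,17.1,2.23,0.404,0.883,51,2.0,0.093
Magnolia salicifolia,Magnoliaceae,W/D,18.3,45.2,2.66,0.179,0.838,104,0.4,0.021
Parrotiopsis jacquemontiana,Hamamelidaceae,W/D,31.5,69.3,2.21,0.221,0.831,161,7.0,0.060
Populus tremula,Salicaceae,W/D,76.9,138.9,1.86,0.183,0.813,258,34.4,0.074
Arbutus unedo,Ericaceae,W/E,31.1,90.8,2.94,0.359,0.851,253,-6.7,0.354
Aucuba japonica,Garryaceae,W/E,26.7,75.1,2.84,0.344,0.865,217,-3.6,0.247
Camellia japonica,Theaceae,W/E,30.9,70.8,2.29,0.541,0.901,247,7.7,0.945
Eucalyptus pauciflora,Myrtaceae,W/E,83.6,176.2,2.15,0.585,0.869,463,26.5,2.925
Hedera helix,Araliaceae,W/E,28.5,68.2,2.41,0.378,0.901,238,5.2,0.296
Ilex aquifolium,Aquifoliaceae,W/E,33.7,90.0,2.71,0.549,0.902,338,0.8,1.221
Rhododendron catawbiense,Ericaceae,W/E,38.1,91.0,2.41,0.378,0.888,298,6.6,0.408
Sarcococca hookeriana,Buxaceae,W/E,19.0,63.6,3.33,0.429,0.903,264,-6.8,0.401
Skimmia japonica,Rutaceae,W/E,19.7,61.1,3.1,0.506,0.912,266,-4.0,0.680
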