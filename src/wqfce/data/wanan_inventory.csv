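source_type,subcategory,pollutant,amount_t_per_a
industrial,industry,CODMn,/
industrial,industry,NH3N,/
industrial,industry,TN,/
industrial,industry,TP,/
agricultural,livestock,CODMn,1146.37
agricultural,livestock,NH3N,231.85
agricultural,livestock,TN,/
agricultural,livestock,TP,7.25
agricultural,aquaculture,CODMn,212.65
agricultural,aquaculture,NH3N,9.82
agricultural,aquaculture,TN,30.90
agricultural,aquaculture,TP,5.69
agricultural,planting,CODMn,/
agricultural,planting,NH3N,/
agricultural,planting,TN,14.01
agricultural,planting,TP,2.54
domestic,urban,CODMn,1775.75
domestic,urban,NH3N,170.26
domestic,urban,TN,233.98
domestic,urban,TP,22.30
domestic,rural,CODMn,546.04
domestic,rural,NH3N,45.73
domestic,rural,TN,69.33
domestic,rural,TP,5.06
centralized,facility,CODMn,1.00
centralized,facility,NH3N,0.10
centralized,facility,TN,0.28
centralized,facility,TP,0.02
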