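variant,canonical
atorvastatin,atorvastatin
lipitor,atorvastatin
simvastatin,simvastatin
zocor,simvastatin
flolipid,simvastatin
lovastatin,lovastatin
mevacor,lovastatin
altoprev,lovastatin
rosuvastatin,rosuvastatin
crestor,rosuvastatin
ezallor,rosuvastatin
pravastatin,pravastatin
pravachol,pravastatin
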