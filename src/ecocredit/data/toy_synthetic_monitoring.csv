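# Synthetic 15-month monitoring log (toy fixture; constructed, not telemetry data)
time_months,plant_id,evidence
0.5,Astrocaryum aculeatissimum,fruit_consumption
1.2,Syagrus romanzoffiana,fruit_consumption
2.0,Inga edulis,fruit_consumption
2.5,Astrocaryum aculeatissimum,seed_burial
3.0,Eugenia uniflora,fruit_consumption
4.0,Sterculia chicha,seed_burial
6.5,Joannesia princeps,seed_burial
9.0,Guarea guidonia,fruit_consumption
13.0,Syagrus romanzoffiana,fruit_consumption
14.5,Lecythis pisonis,fruit_consumption
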