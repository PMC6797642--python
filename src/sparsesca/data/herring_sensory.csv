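sample_id,Ripened,Rawness,Malt,Stockfish smell,Sweetness,Salty,Spice,Softness,Toughness,Watery
230,30.3,14.0,11.7,21.3,3.9,56.9,27.8,36.6,40.0,31.5
231,39.5,6.6,6.7,34.7,1.9,56.6,30.3,37.7,44.2,30.2
232,49.7,3.6,19.5,29.5,5.9,54.1,20.2,47.8,50.7,40.5
233,46.0,4.0,16.0,28.0,7.0,57.0,33.0,53.0,52.0,38.0
234,57.5,1.8,17.7,38.3,10.2,57.5,27.1,52.6,57.8,41.5
235,62.2,2.3,25.6,29.6,12.9,62.2,29.8,57.3,63.0,40.9
236,64.3,4.1,26.8,31.2,14.3,58.2,25.5,65.0,70.4,43.0
238,27.8,13.1,11.8,14.3,6.0,48.7,25.9,38.5,40.4,28.5
239,31.6,2.4,6.3,26.7,3.1,62.1,26.9,37.0,42.1,29.1
240,43.3,3.5,16.2,24.3,6.9,57.3,32.3,45.2,48.8,37.3
241,44.0,1.0,21.0,23.0,10.0,58.0,35.0,52.0,57.0,39.0
242,46.0,5.7,19.3,20.0,14.1,57.2,30.1,61.0,63.2,44.2
243,35.7,2.2,14.7,13.7,12.2,63.4,35.7,49.4,49.5,36.9
244,48.2,4.8,18.1,22.7,16.1,60.7,35.4,62.8,64.8,47.8
286,25.0,13.0,8.0,19.0,7.0,52.0,20.0,29.4,33.0,27.0
287,27.8,5.1,4.8,17.5,7.2,64.9,35.3,40.8,44.1,32.9
288,32.6,8.1,8.6,23.1,9.2,60.5,26.5,37.9,37.9,37.4
289,38.9,7.3,13.4,21.4,12.1,57.5,31.2,47.7,49.2,41.0
290,42.7,8.4,15.3,21.8,7.5,51.0,34.3,50.1,51.5,39.5
291,47.4,5.2,25.5,19.6,13.2,56.9,35.2,62.2,66.4,50.0
292,53.6,0.3,27.3,18.9,13.1,55.3,27.9,66.2,67.5,50.1
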