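sample_id,pHB,ProteinM,ProteinB,Water,AshM,Fat,TCAIndexM,TCAIndexB,TCAM,TCAB
230,5.92,20.48,2.71,49.0,11.45,15.18,14.08,94.28,2.8835,2.555
231,5.89,18.61,4.33,49.91,11.99,15.47,17.26,77.552,3.212,3.358
232,5.87,18.39,5.25,50.77,11.72,14.23,17.268,73.0,3.1755,3.8325
233,5.83,17.97,5.64,51.61,12.09,13.62,19.702,70.541,3.5405,3.9785
234,5.87,17.73,6.07,50.52,12.2,14.29,17.087,72.158,3.0295,4.38
235,5.86,18.06,6.77,51.68,11.84,13.05,22.029,71.167,3.9785,4.818
236,5.9,17.64,6.95,52.4,11.87,13.22,24.209,73.0,4.2705,5.0735
238,5.94,19.69,2.81,49.79,11.11,15.43,13.532,90.925,2.6645,2.555
239,5.91,18.41,4.33,51.83,11.68,13.65,15.663,66.594,2.8835,2.8835
240,5.89,17.12,5.26,52.9,11.95,13.78,18.548,72.861,3.1755,3.8325
241,5.88,17.22,5.6,53.97,11.95,12.41,20.348,65.179,3.504,3.65
242,5.94,17.01,6.05,53.02,11.56,13.31,18.239,67.57,3.1025,4.088
243,6.17,17.91,6.84,54.16,11.28,11.8,18.749,59.232,3.358,4.0515
244,6.06,17.45,6.76,52.92,11.52,13.84,21.963,69.652,3.8325,4.7085
286,6.02,18.7,3.02,54.47,12.17,10.64,10.93,58.013,2.044,1.752
287,5.94,18.24,4.27,55.59,11.99,9.08,10.806,57.272,1.971,2.4455
288,6.0,17.13,4.85,57.69,11.84,8.74,16.407,51.928,2.8105,2.5185
289,5.94,16.95,5.42,55.97,11.98,11.61,18.088,59.935,3.066,3.2485
290,6.01,16.93,5.7,58.21,12.24,8.76,20.266,61.474,3.431,3.504
291,6.09,16.85,5.98,56.28,11.73,10.96,22.312,61.037,3.7595,3.65
292,6.26,16.28,6.96,57.83,11.75,10.13,28.474,66.078,4.6355,4.599
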