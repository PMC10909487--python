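id,start_date,end_date,n_segments,length_mm,growth_days,days_dry,days_wet,days_lactating,rate_printed
WB_417,08/06/2013,02/07/2014,25,200,389,135,254,120,0.514
Wb_418,09/06/2013,03/07/2014,23,184,389,150,239,0,0.473
WB_419,08/06/2013,05/07/2014,24,192,392,144,248,120,0.489
WB_420,10/06/2013,06/07/2014,26,208,391,165,226,120,0.531
WB_422,10/06/2013,06/07/2014,21,168,391,180,211,120,0.429
WB_551,26/05/2016,30/11/2017,37,296,553,345,208,240,0.535
WB_552,26/05/2016,30/11/2017,39,312,553,345,208,0,0.564
WB_553,26/05/2016,29/11/2017,33,264,552,345,207,240,0.478
WB_578,24/03/2018,23/06/2019,36,288,456,210,246,120,0.631
WB_580,27/04/2017,24/06/2019,40,320,788,210,578,120,0.406
WB_582,24/03/2018,25/06/2019,33,264,458,195,263,0,0.576
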