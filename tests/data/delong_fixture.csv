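"y","s1","s2"
0,0.822575068288001,0.907624205882957
0,-0.338818902837653,0.154752862519218
0,0.217877046802404,0.0530641374957518
0,0.379717562976624,-0.0725379225234537
0,0.242560993884599,-0.716597337096317
0,-0.0636747096548904,0.367198138824232
0,0.906913198463363,-0.130283907447912
0,-0.0567954230478585,-0.109654023799153
0,1.21105422832623,0.560007797142696
0,-0.0376284594314526,0.493063866304949
0,0.782921792534091,0.835269825560563
0,1.37198723562066,-0.285704353832805
0,-0.833316420667404,0.390209136435783
0,-0.167273260090423,0.834666273834
0,-0.0799928018361948,-0.666473327668739
0,0.381570238842045,-0.516475552126705
0,-0.170551752849643,-0.679043208512262
0,-1.59387325254287,-0.875528399701437
0,-1.46428015714531,0.0479895319446967
0,0.792068007438115,0.391922603789514
0,-0.183983156447085,0.720579225359096
0,-1.068785060388,0.626850652300635
0,-0.103150413455773,-0.601925188103909
0,0.728804819503559,1.10908914100365
0,1.13711607675898,-0.40006404525469
0,-0.25828147896372,0.0633082874736417
0,-0.154361629661358,-0.253353529121314
0,-1.05789785111687,-0.0734101031729828
0,0.276058412898763,0.112915820700899
0,-0.383996925576072,0.0714965747982038
0,0.273270073944732,-0.0150555305204417
0,0.422902402337291,0.0648436367652195
0,0.621062113181953,-0.291261141508001
0,-0.365355825244327,-0.302530278412742
0,0.302973073978782,-0.996659447948887
0,-1.03020520744401,-0.229400236124291
0,-0.470675405027698,-0.30759015472668
0,-0.510544556505911,1.62113460020688
0,-1.44852458996798,-0.817269738713831
0,0.0216735641353534,0.0823537311351642
1,0.923599160120152,-0.596175040389774
1,0.5833656208708,-0.582261444862078
1,1.25489794141971,0.374821431718204
1,0.363977103754055,-0.297983480930422
1,-0.0209686266515766,0.298906431417175
1,1.05969081553323,0.0430446711445108
1,0.313164094287997,-0.0682029638696972
1,1.66646075703275,-0.914806707251465
1,0.541132278431993,-0.434848770215992
1,1.19338873004132,0.407709864670763
1,0.993155159122368,0.640572356654121
1,0.329696635471775,0.00427358786791515
1,1.74543651187519,0.300037730439211
1,1.18573958343039,0.97373378602798
1,0.853856387959763,1.16391344578571
1,0.965930448374878,-0.358268261043493
1,1.20757328963316,0.229608263849894
1,0.853899731947449,1.02089904055182
1,-0.995854049891761,0.0181622516602195
1,0.970929772118396,0.268518309036602
1,0.579659214355415,0.248335621057746
1,0.911138338919366,-0.232607410743859
1,1.1490942364193,0.0331895970691571
1,1.63984209637561,0.282333072547057
1,0.363624764315321,0.0516786905652459
1,1.58152557922649,0.968031614020922
1,1.00150887185124,0.0114042950076109
1,1.42310365921857,0.0400985804395626
1,1.35243714097439,0.718117545931262
1,1.23252689772012,-0.333821047902545
1,0.174128636859287,0.275580914909271
1,0.745888168033576,-0.630926893408554
1,1.17411089719973,1.00030172954141
1,0.227885985336594,0.135812579175552
1,0.474302711255686,0.0192928051966479
1,1.14859789860901,-0.442951396791729
1,1.26090724270075,0.295342779733604
1,1.0782605531241,-0.180169306770996
1,0.268534221554192,-0.0200953979702619
1,0.140131460811287,1.07260514735075
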