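# synthetic reduced mitochondrial haplogroup tree: name, parent, defining variants (POS+ALT)
name	parent	variants
mt-MRCA		
H	mt-MRCA	8767G,12427G,15909T,11398A,9554T,9907T,15751G,3961T,5917C,608T,15902A,10838G,11573G,9754A,14364G,14317C,2786G
H1	H	8746G,5634A,8424A,14177A,1146G,2775T,3625C,2850T,16235G,15521T,5673G,2067A,13363G,6501A,10063G,10144A,3217C,10508T
H2	H	2805C,14289C,2306C,3516A,13157C,4440C,10487G,14221T,2509A,13126G,468C,11791T,11269A,5637A,4335G,11190T,16003A
H5	H	15455C,8996A,16170A,16479T,12525G,9745G,6222C,7540G,12300T,11288T,14495G,4290G,14438C,4130C,3098C
U	mt-MRCA	7916T,13632A,8254G,679T,3276C,4779T,15570A,7649G,16418G,6880C,8621T,10624A,10642C,4928C,2550T,4960G,8848G,15447A
U2	U	1618A,10095A,11827C,6839T,15482A,14186A,11233C,10042T,13714G,8697G,2814T,6407A,12172G,12323A,12553G
U4	U	11598C,9061G,4158T,12733G,11273T,3796A,16277G,10264C,12963C,12987C,7832C,13099A,15753G,5289A,3952C,14822C,14772T
U5	U	9970T,14013G,1749C,14368C,11799G,5827A,10889T,14994C,6636G,16352A,11225C,15385C,3876C,1997T
J	mt-MRCA	1311A,14021G,16312C,11894C,14171G,15732C,11891T,12744C,6051T,16344G,2176A,15550T,3272C,7997G,4840G
J1	J	14065T,1520T,15563C,8725A,677T,2759T,9155G,7012A,14280C,11861A,15795C,12020T,1819C,11451T
J2	J	12599T,3418G,8893A,12657T,5233G,16299A,11194T,2738T,15135G,12196A,10705G,3627G,15171T,4608G,1037G,9886T,16098C
T	mt-MRCA	15215T,1887T,13724A,2548G,9479C,6220A,14705G,3124C,2069A,6807T,8787T,11203G,15856T,9914G
T1	T	8140A,14611T,8296A,3380T,10526G,1295G,3883G,13446G,2181T,7055C,6105A,8552G,5674C,16313C,12443G
T2	T	3769T,12171T,4384A,4403A,3109T,15920T,4082C,2001C,8029T,12407C,11585G,4900G,8802C,7351G,15831A,16435C
K	mt-MRCA	15381C,4365G,13704T,16387T,8533G,2073A,12466C,8626A,2006G,15235C,9739A,4059A,16382A,8872T,3230C,11396T,6309C,13852A
K1	K	10524G,6272T,2669A,11172T,1811G,9213A,5904C,3458T,10694A,3620G,3652T,12493T,14313C,2965C,12133G,10710G
C	mt-MRCA	1078G,10226A,2356G,12631T,10151G,3661T,11773G,5122T,11249A,1320T,3679G,11222C,3450C,4243G,2343C,13035A
C4	C	3874A,3562A,15031C,10877C,11239C,16047A,7964G,3807A,6171T,15800G,10361A,3165C,4927C,7T,951G
C5	C	4150G,8977C,11275G,5527G,2573C,1158T,7107C,15332G,10493G,11039T,12226T,13384A,6173T,2746A,9234C,15179G,355G,11950G
D	mt-MRCA	241A,16102C,5852G,11373T,2018C,6087C,10278G,11960G,10509A,1023A,1383T,7535G,5117C,14991T
D4	D	4725G,10092G,15687G,12399C,16449G,2334G,4436C,9378C,10087G,14486C,16356T,12499T,16477G,15389T
D5	D	14974C,12642T,11856G,12567G,14116T,15661C,12906G,3206G,2551C,4452A,15583A,4951T,10367C,14935G,13000G,14885C
M	mt-MRCA	2599A,5785C,11784C,2262C,15041G,3125G,15894A,3036G,10262C,12283T,15779C,11125A,14337C,11910A,10959G,11863T,14233A
M7	M	2636G,8276G,4860C,9224A,15450C,10296G,30G,14217A,3534T,2661C,5406A,12982G,1672A,2022C
M8	M	6377C,3825G,15370G,5816G,6994G,15617T,4184A,15378A,10053G,263C,12258C,3791C,4609A,7977A,12380A,11258T,12163G
N	mt-MRCA	4331G,12241G,576G,1945C,8081A,9041G,7575A,2351G,10211G,3243A,12472A,13451G,3890C,4251G,5254A,12089G
N1	N	14908A,2388G,6599C,14632G,5497C,9584G,12712A,678C,10989C,11410G,14610A,514C,15441A,13979C
W	mt-MRCA	12700T,2935T,2647G,8905A,8345G,11857A,4596A,14526C,8128C,1015T,1837C,15405G,8560T,15198C,10037G,4926C,6339G,14923A
W1	W	14648T,11745T,1333C,6970G,3550G,2832G,13232A,8459C,15559G,8589C,16096C,5993T,16346T,14003G,12947T,4598C,11375C,8891A
B	mt-MRCA	2060C,2248G,2905G,14407A,15132T,5032C,15150A,5046A,11713C,6154A,16191T,15556T,643G,808T,9447T,8434T,8967A,12187A
B4	B	16493G,5427G,4291C,14894T,16230G,5824T,7161A,6821G,10515T,11652G,8921A,10326A,10610T,4293T,14272C,7373A,11099C
I	mt-MRCA	3875T,14464G,16316T,5919C,16043T,4415C,2479T,4021T,10314A,4557T,11678G,3112A,5731G,11175G,16005A
I1	I	16257C,11513C,4921A,2898T,3104G,2968C,12289G,6952G,7177T,11704T,11982G,1394T,3316C,5317G,3906G,11899C,14975T,1861T
H1c	H1	13092T,8129T,2937A,15099T,9949T,2461G,3168C,8606C,10506C,16478G,10884G,3055G,10038T,11965C,2973C,3028A,9871A,7275T
H2a	H2	10597G,16376T,14227G,8167G,12120T,2492G,7770G,1185A,14871T,12505C,1352G,14748G,4794T,3292A,16272A,4305G
U5a	U5	13058A,2188A,14331G,3031A,11662A,8019G,14720C,3013C,10140G,7286T,15530T,12745G,661T,2276A,15770C
U5b	U5	7991T,3455T,14597T,11629C,14189C,2597C,14151A,14180G,10561C,9728G,11457C,2744A,16534A,12392A,11216C,13121A,3235C,7751T
J1c	J1	14590T,5836C,3394A,2864A,10382A,16265C,6120T,2214G,14024A,6028T,12293C,12548G,4532A,10951A,5574T
T2b	T2	14853T,657C,4405G,10070C,12064T,12492C,2578A,1668C,14460A,1215T,3030C,13727C,14360A,8986A,12306G,12571G
C4a	C4	2427G,12918C,7742G,1321C,16525G,15096T,11559C,15020C,736G,14766G,16500T,15329A,8534C,2995T,14685T,7310A,12980C
D4a	D4	6963A,14053C,15830C,3180G,374G,675A,12948T,8927A,4978G,15322G,3756G,14465T,13090G,10311C,9127G,2126C,1081C
D4b	D4	3270G,14191G,5712G,4539G,2853C,5488G,11890G,12018C,11355T,2182A,10036C,1351C,3110T,14642A,15187T,11535A,10252G
M8a	M8	8426T,1237C,11503G,3989A,11576G,2045A,10080C,8495C,13954T,3663A,12183A,14742T,12211G,3178A
K1a	K1	1722C,10216A,10541C,11864A,9631T,10421C,3591G,4434T,4071C,12400G,3702G,4873G,16244G,2397C,3506C
H1c4	H1c	11626G,15503G,27G,15410A,3389T,795C,4208G,2103C,14540T,15409G,2130G,2478C,4868G,12626A,10029C,3310C
H2a1	H2a	12032G,446T,2757A,7780A,16049G,13855T,12401C,2400T,15965G,12200G,8039C,4250A,11252G,10001T,4342T,8922T,13467C,9047A
J1c2	J1c	16180C,12282C,4647G,8811G,14592T,4200C,5127A,5621T,11157A,11707G,15942C,7237A,15501C,8975C
D4a1	D4a	5806G,3573T,4392G,14883T,4488T,14744G,15716A,14793T,4483G,4745G,1259A,11927G,8516C,3017A,10739T,4561C,1142C,16508A
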